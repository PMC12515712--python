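"""Shared fixtures: a small seeded reference, a noiseless two-sample
library with germline + somatic insertions, and helpers that compute the
loci the pipeline can observe (with the same poly(A)-boundary
normalization the read parser applies)."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from l1trace.config import PRIMER_LANDING_LEN, SimConfig
from l1trace.ingest import _leading_polya
from l1trace.mapping import build_index
from l1trace.simulate import (SampleSpec, build_loci, plant_insertions,
                              random_insertion_requests, simulate_library,
                              simulate_reference)

SMALL_CFG = SimConfig(seed=7, genome_length=150_000, n_ref_l1=4,
                      genome_equivalents=50, mean_reads_per_molecule=2.0)
NOISELESS_CFG = dataclasses.replace(SMALL_CFG, subst_error_rate=0.0,
                                    chimera_rate=0.0)

SAMPLES = (SampleSpec("s_base", "subjA", "baseline", "untreated"),
           SampleSpec("s_fu", "subjA", "day28", "untreated"))


@pytest.fixture(scope="session")
def small_ref():
    return simulate_reference(SMALL_CFG)


@pytest.fixture(scope="session")
def small_index(small_ref):
    return build_index(small_ref)


@pytest.fixture(scope="session")
def noiseless_truth(small_ref):
    rng = np.random.default_rng([7, 99])
    germ = random_insertion_requests(small_ref, NOISELESS_CFG, rng, 4,
                                     "germline", 1.0, ["s_base", "s_fu"])
    som = random_insertion_requests(small_ref, NOISELESS_CFG, rng, 1,
                                    "somatic", 0.3, ["s_fu"], existing=germ)
    return plant_insertions(small_ref, germ + som, 7, samples=SAMPLES)


@pytest.fixture(scope="session")
def noiseless_lib(small_ref, noiseless_truth):
    return simulate_library(noiseless_truth, small_ref, NOISELESS_CFG)


def normalized_locus_junctions(ref, truth, cfg):
    """[(Locus, observed_junction)] for loci the pipeline can call.

    When a locus's genomic flank itself starts with adenosines, the parser
    cannot separate them from the element's poly(A) tail and trims the
    maximal run; the observed junction shifts past those bases.  Loci whose
    flank drops below the minimum mappable length after that trim are
    unobservable and excluded.
    """
    protocol = cfg.protocol()
    out = []
    for loc in build_loci(ref, truth, cfg):
        polya_len = len(loc.head) - PRIMER_LANDING_LEN
        run = _leading_polya("A" * polya_len + loc.flank,
                             protocol.polya_min_run)
        shift = run - polya_len
        if len(loc.flank) - shift < protocol.min_flank_len:
            continue
        j = loc.junction + shift if loc.strand == "+" else loc.junction - shift
        out.append((loc, j))
    return out
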