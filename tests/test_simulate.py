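"""Simulator: digestion, reference building, insertion planting,
library generation, truth serialization."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from l1trace.config import (DEFAULT_ENZYME_SITES, L1HS_CONSENSUS_3P,
                            PRIMER_LANDING_LEN, SimConfig)
from l1trace.seqs import random_dna
from l1trace.simulate import (PlantedInsertion, SampleSpec, carrier_haplotype,
                              digest, plant_insertions,
                              random_insertion_requests, read_reference,
                              read_truth, simulate_library,
                              simulate_reference, write_library,
                              write_reference, write_truth)
from conftest import NOISELESS_CFG, SAMPLES, SMALL_CFG


# ---------------------------------------------------------------------------
# digest
# ---------------------------------------------------------------------------

def naive_cut_positions(seq, enzyme_sites):
    """Independent oracle: scan every start position for every site."""
    cuts = set()
    for rec, off in enzyme_sites:
        for i in range(len(seq) - len(rec) + 1):
            if seq[i:i + len(rec)] == rec and 0 < i + off < len(seq):
                cuts.add(i + off)
    return sorted(cuts)


def test_digest_no_sites_identity():
    frags = digest("ACGTACGT", DEFAULT_ENZYME_SITES)
    assert [f.seq for f in frags] == ["ACGTACGT"]
    assert (frags[0].start, frags[0].end) == (0, 8)


def test_digest_taqi_example():
    assert [f.seq for f in digest("TTCGAA", DEFAULT_ENZYME_SITES)] == ["TT", "CGAA"]


def test_digest_fspbi_example():
    assert [f.seq for f in digest("GCTAGC", DEFAULT_ENZYME_SITES)] == ["GC", "TAGC"]


def test_digest_rejects_non_dna():
    with pytest.raises(ValueError):
        digest("ACGTN", DEFAULT_ENZYME_SITES)


def test_digest_partition_property_vs_oracle():
    rng = np.random.default_rng(11)
    site_sets = [DEFAULT_ENZYME_SITES, (("TCGA", 1),), (("AA", 0),),
                 (("ACG", 2), ("GT", 1))]
    for trial in range(300):
        n = int(rng.integers(1, 120))
        seq = random_dna(rng, n)
        sites = site_sets[trial % len(site_sets)]
        frags = digest(seq, sites)
        # fragments tile the input exactly
        assert "".join(f.seq for f in frags) == seq
        assert frags[0].start == 0 and frags[-1].end == n
        for a, b in zip(frags, frags[1:]):
            assert a.end == b.start
        # boundaries equal the naive site scan
        assert [f.end for f in frags[:-1]] == naive_cut_positions(seq, sites)


# ---------------------------------------------------------------------------
# reference simulation
# ---------------------------------------------------------------------------

def test_simulate_reference_seeded_determinism():
    a = simulate_reference(SMALL_CFG)
    b = simulate_reference(SMALL_CFG)
    assert a.contigs == b.contigs
    assert a.l1_catalogue == b.l1_catalogue
    assert len(a.l1_catalogue) == SMALL_CFG.n_ref_l1


def test_simulate_reference_no_copies():
    ref = simulate_reference(dataclasses.replace(SMALL_CFG, n_ref_l1=0))
    assert ref.l1_catalogue == ()
    assert len(ref.contigs["chr1"]) == SMALL_CFG.genome_length


def test_simulate_reference_seed_changes_positions_not_count():
    a = simulate_reference(SMALL_CFG)
    b = simulate_reference(dataclasses.replace(SMALL_CFG, seed=8))
    assert len(a.l1_catalogue) == len(b.l1_catalogue)
    assert ([c.start for c in a.l1_catalogue]
            != [c.start for c in b.l1_catalogue])


def test_simulate_reference_too_small_raises():
    with pytest.raises(ValueError, match="too small"):
        simulate_reference(dataclasses.replace(SMALL_CFG, genome_length=20_000,
                                               n_ref_l1=10))


def test_amplifiable_copies_keep_landing(small_ref):
    landing = L1HS_CONSENSUS_3P[-PRIMER_LANDING_LEN:]
    from l1trace.seqs import revcomp
    for copy in small_ref.l1_catalogue:
        seq = small_ref.contigs[copy.contig]
        polya = SMALL_CFG.ref_polya_len
        if copy.strand == "+":
            seg = seq[copy.end - polya - PRIMER_LANDING_LEN:copy.end - polya]
        else:
            seg = revcomp(seq[copy.start + polya:copy.start + polya
                              + PRIMER_LANDING_LEN])
        assert (seg == landing) == copy.is_amplifiable


# ---------------------------------------------------------------------------
# planting insertions
# ---------------------------------------------------------------------------

def _ins(pos, strand="+", l1=300, polya=20, tsd=12, origin="germline",
         fraction=1.0, scope=("s_base", "s_fu")):
    return PlantedInsertion("chr1", pos, strand, l1, polya, tsd, origin,
                            fraction, tuple(scope))


def test_carrier_haplotype_length_arithmetic(small_ref):
    ins = _ins(120_000)
    hap = carrier_haplotype(small_ref, "chr1", [ins])
    base = small_ref.contigs["chr1"]
    assert len(hap) == len(base) + ins.l1_length + ins.polya_len + ins.tsd_len
    # structure: genome | TSD | L1 tail | poly(A) | TSD | genome
    p, t = ins.target_pos, ins.tsd_len
    assert hap[:p] == base[:p]
    assert hap[p:p + t] == base[p:p + t]
    assert hap[p + t:p + t + ins.l1_length] == L1HS_CONSENSUS_3P[-ins.l1_length:]
    assert hap[p + t + ins.l1_length:p + t + ins.l1_length + ins.polya_len] \
        == "A" * ins.polya_len
    assert hap[-(len(base) - p):] == base[p:]


def test_blunt_insertion_allowed(small_ref):
    truth = plant_insertions(small_ref, [_ins(120_000, polya=0, tsd=0)], 1,
                             samples=SAMPLES)
    assert truth.insertions[0].breakpoint == 120_000


def test_plant_rejects_overlap(small_ref):
    with pytest.raises(ValueError, match="overlap"):
        plant_insertions(small_ref, [_ins(120_000), _ins(120_005)], 1,
                         samples=SAMPLES)


def test_plant_rejects_inside_reference_copy(small_ref):
    copy = small_ref.l1_catalogue[0]
    with pytest.raises(ValueError, match="reference L1 copy"):
        plant_insertions(small_ref, [_ins(copy.start + 5)], 1, samples=SAMPLES)


def test_plant_rejects_out_of_bounds(small_ref):
    with pytest.raises(ValueError, match="bounds"):
        plant_insertions(small_ref, [_ins(10**9)], 1, samples=SAMPLES)


def test_plant_rejects_bad_fraction():
    with pytest.raises(ValueError):
        _ins(1000, origin="somatic", fraction=0.0)
    with pytest.raises(ValueError):
        _ins(1000, origin="germline", fraction=0.5)


def test_breakpoint_geometry():
    assert _ins(1000, strand="+", tsd=12).breakpoint == 1000
    assert _ins(1000, strand="-", tsd=12).breakpoint == 1012


# ---------------------------------------------------------------------------
# truth serialization
# ---------------------------------------------------------------------------

def test_truth_round_trip(tmp_path, noiseless_truth):
    bed, tsv = tmp_path / "t.bed", tmp_path / "t.tsv"
    write_truth(noiseless_truth, bed, tsv)
    back = read_truth(tsv)
    assert back == dataclasses.replace(
        noiseless_truth,
        insertions=tuple(sorted(noiseless_truth.insertions,
                                key=lambda i: (i.contig, i.target_pos))))
    assert len(bed.read_text().splitlines()) == len(noiseless_truth.insertions)


def test_truth_empty(tmp_path):
    from l1trace.simulate import TruthSet
    bed, tsv = tmp_path / "t.bed", tmp_path / "t.tsv"
    write_truth(TruthSet((), SAMPLES, 3), bed, tsv)
    assert bed.read_text() == ""
    assert read_truth(tsv) == TruthSet((), SAMPLES, 3)


def test_truth_bed_sorted(tmp_path, small_ref):
    truth = plant_insertions(
        small_ref, [_ins(130_000), _ins(120_000), _ins(125_000)], 1,
        samples=SAMPLES)
    bed, tsv = tmp_path / "t.bed", tmp_path / "t.tsv"
    write_truth(truth, bed, tsv)
    starts = [int(l.split("\t")[1]) for l in bed.read_text().splitlines()]
    assert starts == sorted(starts) and len(starts) == 3


def test_reference_round_trip(tmp_path, small_ref):
    fa, bed = tmp_path / "ref.fa", tmp_path / "cat.bed"
    write_reference(small_ref, fa, bed)
    back = read_reference(fa, bed)
    assert back.contigs == small_ref.contigs
    assert set(back.l1_catalogue) == set(small_ref.l1_catalogue)


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

def test_library_read_lengths(noiseless_lib):
    for pairs in noiseless_lib.reads.values():
        for _rid, s1, q1, s2, q2 in pairs[:200]:
            assert len(s1) == len(q1) == 150
            assert len(s2) == len(q2) == 150


def test_library_seeded_determinism(tmp_path, small_ref, noiseless_truth):
    a = simulate_library(noiseless_truth, small_ref, NOISELESS_CFG)
    b = simulate_library(noiseless_truth, small_ref, NOISELESS_CFG)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    pa, pb = write_library(a, d1), write_library(b, d2)
    for sample in pa:
        for i in (0, 1):
            assert pa[sample][i].read_bytes() == pb[sample][i].read_bytes()


def test_empty_library_warning():
    cfg = dataclasses.replace(SMALL_CFG, n_ref_l1=0)
    ref = simulate_reference(cfg)
    from l1trace.simulate import TruthSet
    import logging
    truth = TruthSet((), SAMPLES, 7)
    lib = simulate_library(truth, ref, cfg)
    assert all(len(v) == 0 for v in lib.reads.values())
    assert len(lib.manifest) == 0


def test_germline_locus_molecule_support(noiseless_lib):
    man = noiseless_lib.manifest
    germ = man[(man.origin == "germline") & (man.sample_id == "s_base")]
    # every germline locus yields >= 2 distinct molecules at default depth
    per_locus = germ.groupby("locus_id")["umi"].nunique()
    assert (per_locus >= 2).all()


def test_somatic_absent_from_baseline(noiseless_lib):
    man = noiseless_lib.manifest
    assert (man[man.origin == "somatic"].sample_id == "s_fu").all()


def test_cell_fraction_consistency():
    """Observed somatic molecule fraction matches cell_fraction within 3 sd."""
    fraction, n_seeds = 0.2, 24
    total_mol, total_draws = 0, 0
    for seed in range(n_seeds):
        cfg = dataclasses.replace(NOISELESS_CFG, seed=seed)
        ref = simulate_reference(cfg)
        rng = np.random.default_rng([seed, 42])
        som = random_insertion_requests(ref, cfg, rng, 1, "somatic", fraction,
                                        ["s_fu"])
        truth = plant_insertions(ref, som, seed, samples=SAMPLES)
        lib = simulate_library(truth, ref, cfg)
        man = lib.manifest
        total_mol += len(man[(man.origin == "somatic")
                             & (man.sample_id == "s_fu")])
        total_draws += cfg.genome_equivalents
    observed = total_mol / total_draws
    sd = (fraction * (1 - fraction) / total_draws) ** 0.5
    assert abs(observed - fraction) <= 3 * sd


def test_random_insertion_requests_respect_spacing(small_ref):
    rng = np.random.default_rng(3)
    reqs = random_insertion_requests(small_ref, SMALL_CFG, rng, 6, "germline",
                                     1.0, ["s_base"], min_spacing=2500)
    positions = sorted(r.target_pos for r in reqs)
    assert all(b - a >= 2500 for a, b in zip(positions, positions[1:]))
    for r in reqs:
        for copy in small_ref.l1_catalogue:
            assert not (copy.start - 2500 <= r.target_pos < copy.end + 2500)
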