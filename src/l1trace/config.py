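"""Configuration objects and protocol constants.

The library models a targeted L1HS 3'-junction protocol: genomic DNA is
digested with two four-cutter endonucleases (TaqI, FspBI), fragments are
ligated to a UMI-bearing stem-loop adapter, and the 3' end of the
human-specific L1 subfamily plus its downstream genomic flank is amplified
with a semi-nested L1HS-specific primer before 150+150 paired-end
sequencing.  The published protocol does not disclose its primer, adapter
or UMI design, so the sequences below are explicit surrogates: fixed,
documented constants with the structural properties the simulator and the
read parser need (no internal TaqI/FspBI site, a dedicated 25 nt primer
landing at the consensus 3' end).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Sequence

logger = logging.getLogger("l1trace")

DNA_ALPHABET = "ACGT"

#: Surrogate 600 nt L1HS 3'-end consensus (the transpositionally active
#: subfamily targeted by the amplification primer).  Free of TaqI (TCGA)
#: and FspBI (CTAG) recognition sites so digestion never severs the primer
#: landing from the junction.
L1HS_CONSENSUS_3P = (
    "CCTACCGAAGAGAAATTAATGCTTAGACCGTGGATAGATACAGAAACTGCCGCCTAAATG"
    "ACTAACCGTGAACGGTAATGGGCTAAAGCGCTTACTCTTAGAGCGAGGCCGAGTCAGTTC"
    "TCTACGCTAACCACTTGGGGCGCACGGCATCCGGACACTTGAGTAGAACTGACACGGCCT"
    "TCCAAAGGCAGGTATCCGAAGTAAGCAAAGATCCGTTGAGAGTACATGGATTGAGTATCT"
    "CTGAAAACACGTAGTTGGCCGGGGAGGCAGCTGGACTCTACAGATAGTGAAGTACGGGGT"
    "TAAAGTGACAGGGCACGCGTAGCATCCGGCGTCAGTGTGAACGCGAGCAGCGCAAGGGAG"
    "CGGCCACCGCACCGAGAAGGCGCTCTTGAATGTCAATGTAGTCTTCTACTGCTCGCTCCC"
    "CATTAGGAGCTTAGAGGGTAGAGAGATTGGGTTGCCACTGCGGAACATATAAATTAACCG"
    "CCCAGAGGATAGAATGTTGATAAGGCCTGCCCCGGCGATAAATGAAGGCTTGGATAGAGC"
    "CTTACCCCGGTACTCCGAGTTTTACATAGATAAGCGTCCTGACTCAAGCCGCCGGTGATC"
)

#: Length of the inner (semi-nested) primer landing at the consensus 3' end.
PRIMER_LANDING_LEN = 25

#: The landing itself; every amplified molecule starts with this sequence.
L1HS_PRIMER_LANDING = L1HS_CONSENSUS_3P[-PRIMER_LANDING_LEN:]

#: Surrogate 40 nt stem-loop adapter constant preceding the UMI on the
#: adapter-side mate.  Site-free for the same reason as the consensus.
ADAPTER_STEM = "CTATGACATGAGTAGCTTGGATGAACAAGAGGCTGGATTC"

#: TaqI T^CGA and FspBI (MaeI isoschizomer) C^TAG: (recognition, cut offset).
DEFAULT_ENZYME_SITES: tuple[tuple[str, int], ...] = (("TCGA", 1), ("CTAG", 1))


@dataclass(frozen=True)
class ProtocolConfig:
    """Read-architecture constants shared by simulator and parser.

    The adapter-side mate reads stem + UMI + reverse-complemented fragment;
    the L1-side mate reads primer landing + poly(A) + genomic flank.
    """

    stem: str = ADAPTER_STEM
    umi_len: int = 8
    landing: str = L1HS_PRIMER_LANDING
    read_len: int = 150
    min_flank_len: int = 20
    l1_min_match: int = 15
    l1_max_mismatch_frac: float = 0.10
    polya_min_run: int = 5
    stem_max_mismatch: int = 1

    def validate(self) -> list[str]:
        issues = []
        if not (1 <= self.umi_len <= 24):
            issues.append("protocol.umi_len: expected 1..24")
        if self.min_flank_len < 1:
            issues.append("protocol.min_flank_len: must be >= 1")
        if self.l1_min_match > len(self.landing):
            issues.append("protocol.l1_min_match: exceeds primer landing length")
        if self.read_len < len(self.stem) + self.umi_len + self.min_flank_len:
            issues.append("protocol.read_len: too short for stem+UMI+flank")
        return issues


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the in-silico library.

    Defaults reproduce a desk-scale version of the assay: a 2 Mb genome
    stand-in with 30 reference L1HS copies, 1000 genome equivalents per
    library (so a 1 %-of-cells insertion is expected in ~10 molecules) and
    a mean PCR duplication of 3 reads per original molecule.
    """

    seed: int = 0
    genome_length: int = 2_000_000
    n_ref_l1: int = 30
    amplifiable_fraction: float = 0.8
    umi_len: int = 8
    read_len: int = 150
    genome_equivalents: int = 1000
    mean_reads_per_molecule: float = 3.0
    subst_error_rate: float = 0.001
    chimera_rate: float = 0.002
    enzyme_sites: tuple[tuple[str, int], ...] = DEFAULT_ENZYME_SITES
    copy_divergence: float = 0.015   # per-base substitutions between ref copies
    ref_polya_len: int = 15          # poly(A) retained by reference copies
    min_copy_spacing: int = 5_000
    flank_window: int = 2_000        # how far past a junction fragments are searched

    def validate(self) -> list[str]:
        issues = []
        for name in ("genome_length", "n_ref_l1", "umi_len", "read_len",
                     "genome_equivalents", "ref_polya_len", "flank_window"):
            if getattr(self, name) < 0:
                issues.append(f"sim.{name}: must be >= 0")
        if self.genome_equivalents < 1:
            issues.append("sim.genome_equivalents: must be >= 1")
        for name in ("subst_error_rate", "chimera_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                issues.append(f"sim.{name}: must lie in [0, 1)")
        if not (0.0 <= self.amplifiable_fraction <= 1.0):
            issues.append("sim.amplifiable_fraction: must lie in [0, 1]")
        if self.mean_reads_per_molecule <= 0:
            issues.append("sim.mean_reads_per_molecule: must be > 0")
        for rec, off in self.enzyme_sites:
            if not rec or any(c not in DNA_ALPHABET for c in rec):
                issues.append(f"sim.enzyme_sites: bad recognition {rec!r}")
            if not (0 <= off <= len(rec)):
                issues.append(f"sim.enzyme_sites: cut offset {off} outside {rec!r}")
        return issues

    def protocol(self) -> ProtocolConfig:
        return ProtocolConfig(umi_len=self.umi_len, read_len=self.read_len)


@dataclass(frozen=True)
class MapperParams:
    """Seed-and-extend parameters for the built-in flank aligner."""

    k: int = 15
    n_seeds: int = 8
    max_hits_per_seed: int = 32
    max_candidates: int = 6
    min_identity: float = 0.90
    uniqueness_margin: int = 5
    max_span: int = 600  # mate concordance distance (amplicon scale)

    def validate(self) -> list[str]:
        issues = []
        if self.k < 11:
            issues.append("mapper.k: must be >= 11")
        if not (0.0 < self.min_identity <= 1.0):
            issues.append("mapper.min_identity: must lie in (0, 1]")
        if self.uniqueness_margin < 0:
            issues.append("mapper.uniqueness_margin: must be >= 0")
        return issues


@dataclass(frozen=True)
class FilterConfig:
    """Candidate-selection cascade thresholds.

    ``min_reads_exclusive`` and ``min_umis`` carry the assay's published
    evidence thresholds: a candidate needs read support strictly greater
    than 10 and at least 2 distinct molecules (UMIs).
    """

    match_window: int = 25
    min_reads_exclusive: int = 10
    min_umis: int = 2
    min_concordant_fraction: float = 0.5
    exclude_known_l1: bool = True
    cluster_window: int = 15
    known_l1_margin: int = 100

    def validate(self) -> list[str]:
        issues = []
        for name in ("match_window", "min_reads_exclusive", "min_umis",
                     "cluster_window", "known_l1_margin"):
            if getattr(self, name) < 0:
                issues.append(f"filters.{name}: must be >= 0")
        if not (0.0 <= self.min_concordant_fraction <= 1.0):
            issues.append("filters.min_concordant_fraction: must lie in [0, 1]")
        return issues


def _from_mapping(cls, data):
    """Build a config dataclass from a plain dict, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"{cls.__name__}: unknown keys {sorted(unknown)}")
    if "enzyme_sites" in data:
        data = dict(data)
        data["enzyme_sites"] = tuple((str(r), int(o)) for r, o in data["enzyme_sites"])
    return cls(**data)


def sim_config_from_dict(data: dict) -> SimConfig:
    return _from_mapping(SimConfig, data)


def protocol_from_dict(data: dict) -> ProtocolConfig:
    return _from_mapping(ProtocolConfig, data)


def mapper_params_from_dict(data: dict) -> MapperParams:
    return _from_mapping(MapperParams, data)


def filter_config_from_dict(data: dict) -> FilterConfig:
    return _from_mapping(FilterConfig, data)
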