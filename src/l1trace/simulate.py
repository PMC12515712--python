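"""In-silico L1HS-targeted UMI amplicon libraries.

This module stands in for the wet-lab protocol: it builds a reference
genome stand-in with embedded L1HS 3' copies, plants germline and somatic
insertions (with target-site duplications, 5'-truncation and poly(A)
tails) at specified cell fractions, and emits paired-end FASTQ libraries
that follow the assay's read architecture:

* restriction digestion with TaqI + FspBI defines one fragment per
  amplifiable L1 3' junction per genome copy;
* every original molecule gets a fresh UMI behind the stem-loop adapter;
* PCR duplication is Poisson per molecule; substitution errors and
  fragment-level chimeras model library noise;
* mate 1 reads primer landing + poly(A) + genomic flank, mate 2 reads
  adapter stem + UMI + reverse-complemented fragment, both 150 nt.

A machine-readable truth set (planted insertions and a per-molecule
manifest) accompanies every library so downstream calls can be scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import (
    DNA_ALPHABET,
    L1HS_CONSENSUS_3P,
    PRIMER_LANDING_LEN,
    ProtocolConfig,
    SimConfig,
)
from .seqs import decode, encode, random_dna, revcomp

logger = logging.getLogger("l1trace.simulate")

__all__ = [
    "RefL1Copy", "ReferenceAssembly", "PlantedInsertion", "SampleSpec",
    "TruthSet", "Fragment", "Locus", "LibraryResult",
    "simulate_reference", "digest", "plant_insertions", "carrier_haplotype",
    "random_insertion_requests", "build_loci", "simulate_library",
    "write_truth", "read_truth", "write_reference", "read_reference",
    "write_fastq_pair", "write_library",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RefL1Copy:
    """A reference (population) L1HS 3' segment embedded in the assembly."""

    contig: str
    start: int
    end: int
    strand: str
    is_amplifiable: bool

    @property
    def junction(self) -> int:
        """Genomic coordinate of the element's 3' junction with its flank."""
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class ReferenceAssembly:
    contigs: dict[str, str]
    l1_catalogue: tuple[RefL1Copy, ...]

    def validate(self) -> None:
        if len(set(self.contigs)) != len(self.contigs):
            raise ValueError("duplicate contig names")
        for name, seq in self.contigs.items():
            if not seq or any(c not in DNA_ALPHABET for c in set(seq)):
                raise ValueError(f"contig {name}: empty or non-ACGT sequence")
        for copy in self.l1_catalogue:
            if copy.contig not in self.contigs:
                raise ValueError(f"catalogue copy on unknown contig {copy.contig}")
            if not (0 <= copy.start < copy.end <= len(self.contigs[copy.contig])):
                raise ValueError(f"catalogue interval out of bounds: {copy}")
            if copy.end - copy.start < PRIMER_LANDING_LEN:
                raise ValueError(f"catalogue segment shorter than primer landing: {copy}")


@dataclass(frozen=True)
class PlantedInsertion:
    """A germline or somatic de novo L1 insertion request / truth record."""

    contig: str
    target_pos: int
    strand: str
    l1_length: int
    polya_len: int
    tsd_len: int
    origin: str                      # "germline" | "somatic"
    cell_fraction: float
    sample_scope: tuple[str, ...]    # sample ids carrying the insertion

    def __post_init__(self):
        if self.origin not in ("germline", "somatic"):
            raise ValueError(f"origin must be germline|somatic, got {self.origin!r}")
        if not (0.0 < self.cell_fraction <= 1.0):
            raise ValueError("cell_fraction must lie in (0, 1]")
        if self.origin == "germline" and self.cell_fraction != 1.0:
            raise ValueError("germline insertions have cell_fraction 1.0")
        if self.tsd_len < 0 or self.polya_len < 0:
            raise ValueError("tsd_len and polya_len must be >= 0")
        if not (PRIMER_LANDING_LEN <= self.l1_length <= len(L1HS_CONSENSUS_3P)):
            raise ValueError(
                f"l1_length must lie in [{PRIMER_LANDING_LEN}, {len(L1HS_CONSENSUS_3P)}]")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    @property
    def breakpoint(self) -> int:
        """Junction coordinate recovered by 3'-flank sequencing.

        For '+' insertions the sequenced flank starts at ``target_pos``;
        for '-' insertions the element's 3' junction sits past the first
        TSD copy, at ``target_pos + tsd_len``.
        """
        return self.target_pos if self.strand == "+" else self.target_pos + self.tsd_len

    def element_seq(self) -> str:
        """The inserted sequence (truncated L1 + poly(A)), genome-forward."""
        body = L1HS_CONSENSUS_3P[-self.l1_length:] + "A" * self.polya_len
        return body if self.strand == "+" else revcomp(body)


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    subject: str = "subject1"
    timepoint: str = "baseline"
    condition: str = "untreated"


@dataclass(frozen=True)
class TruthSet:
    insertions: tuple[PlantedInsertion, ...]
    samples: tuple[SampleSpec, ...]
    seed: int


@dataclass(frozen=True)
class Fragment:
    """A restriction fragment with 0-based half-open source coordinates."""
    start: int
    end: int
    seq: str


# ---------------------------------------------------------------------------
# reference simulation
# ---------------------------------------------------------------------------

def _mutate_segment(rng: np.random.Generator, seq: str, rate: float,
                    protect_tail: int) -> str:
    """Substitute bases at `rate`, leaving the last `protect_tail` intact."""
    codes = encode(seq).copy()
    n = len(codes) - protect_tail
    if n <= 0 or rate <= 0:
        return seq
    hit = np.flatnonzero(rng.random(n) < rate)
    codes[hit] = (codes[hit] + rng.integers(1, 4, hit.size, dtype=np.uint8)) % 4
    return decode(codes)


def simulate_reference(cfg: SimConfig) -> ReferenceAssembly:
    """Random genome stand-in with ``cfg.n_ref_l1`` embedded L1HS 3' copies.

    Copies share the surrogate consensus at >= ~97% identity (default
    divergence 1.5%); amplifiable copies keep the primer landing intact,
    non-amplifiable ones have it scrambled so the primer cannot bind.
    Deterministic for a given config.
    """
    issues = cfg.validate()
    if issues:
        raise ValueError("; ".join(issues))
    rng = np.random.default_rng([cfg.seed, 1])
    n = cfg.n_ref_l1
    max_seg = len(L1HS_CONSENSUS_3P) + cfg.ref_polya_len
    if n > 0:
        bin_size = cfg.genome_length // n
        if bin_size < max_seg + cfg.min_copy_spacing:
            raise ValueError(
                f"genome_length {cfg.genome_length} too small to host {n} "
                f"copies with spacing {cfg.min_copy_spacing}")
    genome = encode(random_dna(rng, cfg.genome_length)).copy()

    amplifiable = np.zeros(n, dtype=bool)
    amplifiable[: int(round(n * cfg.amplifiable_fraction))] = True
    amplifiable = amplifiable[rng.permutation(n)] if n else amplifiable

    catalogue = []
    contig = "chr1"
    for i in range(n):
        bin_size = cfg.genome_length // n
        tail_len = int(rng.integers(200, len(L1HS_CONSENSUS_3P) + 1))
        seg_len = tail_len + cfg.ref_polya_len
        lo = i * bin_size
        hi = (i + 1) * bin_size - seg_len - cfg.min_copy_spacing // 2
        start = int(rng.integers(lo, max(lo + 1, hi)))
        strand = "+" if rng.random() < 0.5 else "-"
        tail = _mutate_segment(rng, L1HS_CONSENSUS_3P[-tail_len:],
                               cfg.copy_divergence,
                               PRIMER_LANDING_LEN if amplifiable[i] else 0)
        if not amplifiable[i]:
            # scramble the primer landing so this copy never amplifies
            tail = tail[:-PRIMER_LANDING_LEN] + random_dna(rng, PRIMER_LANDING_LEN)
        seg = tail + "A" * cfg.ref_polya_len
        if strand == "-":
            seg = revcomp(seg)
        genome[start:start + seg_len] = encode(seg)
        catalogue.append(RefL1Copy(contig, start, start + seg_len, strand,
                                   bool(amplifiable[i])))
    ref = ReferenceAssembly(contigs={contig: decode(genome)},
                            l1_catalogue=tuple(catalogue))
    ref.validate()
    return ref


# ---------------------------------------------------------------------------
# restriction digestion
# ---------------------------------------------------------------------------

def cut_positions(seq: str, enzyme_sites: Sequence[tuple[str, int]]) -> list[int]:
    """All cut coordinates (0-based, between-base) on ``seq``, sorted."""
    cuts: set[int] = set()
    for recognition, offset in enzyme_sites:
        i = seq.find(recognition)
        while i != -1:
            pos = i + offset
            if 0 < pos < len(seq):
                cuts.add(pos)
            i = seq.find(recognition, i + 1)
    return sorted(cuts)


def digest(seq: str, enzyme_sites: Sequence[tuple[str, int]]) -> list[Fragment]:
    """Cut ``seq`` at every enzyme recognition site; fragments tile the input."""
    if any(c not in DNA_ALPHABET for c in set(seq)):
        raise ValueError("digest: sequence must be uppercase ACGT")
    bounds = [0, *cut_positions(seq, enzyme_sites), len(seq)]
    return [Fragment(a, b, seq[a:b]) for a, b in zip(bounds, bounds[1:]) if b > a]


# ---------------------------------------------------------------------------
# planting insertions
# ---------------------------------------------------------------------------

def plant_insertions(ref: ReferenceAssembly,
                     requests: Sequence[PlantedInsertion],
                     seed: int,
                     samples: Sequence[SampleSpec] | None = None) -> TruthSet:
    """Validate insertion requests against the reference and freeze a truth set.

    Insertions materialize in carrier haplotypes as TSD + truncated L1 +
    poly(A) + TSD (see :func:`carrier_haplotype`); the returned truth set
    is what the library simulator and the scoring code consume.
    """
    by_contig: dict[str, list[PlantedInsertion]] = {}
    for ins in requests:
        if ins.contig not in ref.contigs:
            raise ValueError(f"insertion on unknown contig {ins.contig}")
        L = len(ref.contigs[ins.contig])
        if not (0 <= ins.target_pos and ins.target_pos + ins.tsd_len <= L):
            raise ValueError(f"insertion out of contig bounds: {ins}")
        for copy in ref.l1_catalogue:
            if copy.contig == ins.contig and copy.start <= ins.target_pos < copy.end:
                raise ValueError(
                    f"insertion at {ins.contig}:{ins.target_pos} lies inside a "
                    f"reference L1 copy [{copy.start},{copy.end})")
        by_contig.setdefault(ins.contig, []).append(ins)
    for contig, group in by_contig.items():
        group = sorted(group, key=lambda i: i.target_pos)
        for a, b in zip(group, group[1:]):
            if b.target_pos < a.target_pos + max(a.tsd_len, 1):
                raise ValueError(
                    f"planted insertions overlap on {contig}: "
                    f"{a.target_pos} and {b.target_pos}")
    if samples is None:
        ids = sorted({s for ins in requests for s in ins.sample_scope})
        samples = tuple(SampleSpec(sample_id=s, timepoint=s) for s in ids)
    return TruthSet(insertions=tuple(requests), samples=tuple(samples), seed=seed)


def carrier_haplotype(ref: ReferenceAssembly, contig: str,
                      insertions: Sequence[PlantedInsertion]) -> str:
    """Contig sequence with the given insertions materialized.

    Each insertion contributes ``TSD | truncated L1 | poly(A) | TSD`` at its
    target position, lengthening the haplotype by
    ``l1_length + polya_len + tsd_len``.
    """
    seq = ref.contigs[contig]
    for ins in sorted(insertions, key=lambda i: -i.target_pos):
        if ins.contig != contig:
            raise ValueError("insertion on a different contig")
        p, t = ins.target_pos, ins.tsd_len
        seq = seq[:p] + seq[p:p + t] + ins.element_seq() + seq[p:]
    return seq


# ---------------------------------------------------------------------------
# amplifiable molecules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Locus:
    """An amplifiable L1 3' junction and the molecule it yields on digestion."""

    locus_id: str
    contig: str
    junction: int
    strand: str
    origin: str                  # "reference" | "germline" | "somatic"
    cell_fraction: float
    sample_scope: tuple[str, ...] | None   # None = every sample
    head: str                    # primer landing + poly(A), molecule-forward
    flank: str                   # genomic flank from junction to first cut

    @property
    def molecule(self) -> str:
        return self.head + self.flank


def _flank_from(contig_seq: str, junction: int, strand: str, head: str,
                enzyme_sites, window: int) -> str:
    """Genomic flank downstream of a junction, truncated at the first cut.

    The cut search runs over head+flank so sites spanning the junction are
    honoured; the head itself is site-free by construction.
    """
    if strand == "+":
        raw = contig_seq[junction:junction + window]
    else:
        raw = revcomp(contig_seq[max(0, junction - window):junction])
    s = head + raw
    cuts = cut_positions(s, enzyme_sites)
    end = cuts[0] if cuts else len(s)
    return s[len(head):end] if end > len(head) else ""


def build_loci(ref: ReferenceAssembly, truth: TruthSet, cfg: SimConfig) -> list[Locus]:
    """Enumerate every amplifiable junction: reference copies + planted insertions."""
    landing = L1HS_CONSENSUS_3P[-PRIMER_LANDING_LEN:]
    loci: list[Locus] = []
    for i, copy in enumerate(ref.l1_catalogue):
        if not copy.is_amplifiable:
            continue
        seq = ref.contigs[copy.contig]
        # the landing and poly(A) sit inside the embedded segment
        if copy.strand == "+":
            head = seq[copy.end - cfg.ref_polya_len - PRIMER_LANDING_LEN:copy.end]
        else:
            head = revcomp(seq[copy.start:copy.start + cfg.ref_polya_len
                               + PRIMER_LANDING_LEN])
        flank = _flank_from(seq, copy.junction, copy.strand, head,
                            cfg.enzyme_sites, cfg.flank_window)
        loci.append(Locus(f"ref{i:03d}", copy.contig, copy.junction, copy.strand,
                          "reference", 1.0, None, head, flank))
    for j, ins in enumerate(truth.insertions):
        seq = ref.contigs[ins.contig]
        head = landing + "A" * ins.polya_len
        flank = _flank_from(seq, ins.breakpoint, ins.strand, head,
                            cfg.enzyme_sites, cfg.flank_window)
        loci.append(Locus(f"ins{j:03d}", ins.contig, ins.breakpoint, ins.strand,
                          ins.origin, ins.cell_fraction,
                          tuple(ins.sample_scope), head, flank))
    loci.sort(key=lambda l: (l.contig, l.junction, l.locus_id))
    return loci


def random_insertion_requests(ref: ReferenceAssembly, cfg: SimConfig,
                              rng: np.random.Generator, n: int, origin: str,
                              cell_fraction: float,
                              sample_scope: Sequence[str],
                              min_flank: int = 40,
                              min_spacing: int = 2500,
                              existing: Sequence[PlantedInsertion] = (),
                              ) -> list[PlantedInsertion]:
    """Draw ``n`` insertion requests at sites the protocol can observe.

    Placement is rejection-sampled so each junction's restriction fragment
    leaves a mappable genomic flank of at least ``min_flank`` nt and sites
    keep ``min_spacing`` nt from reference copies and from each other.
    """
    contig = next(iter(ref.contigs))
    seq = ref.contigs[contig]
    landing = L1HS_CONSENSUS_3P[-PRIMER_LANDING_LEN:]
    taken = [(c.start - min_spacing, c.end + min_spacing) for c in ref.l1_catalogue]
    taken += [(i.target_pos - min_spacing, i.target_pos + min_spacing)
              for i in existing]
    out: list[PlantedInsertion] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * max(n, 1):
            raise RuntimeError("could not place insertions; genome too crowded")
        p = int(rng.integers(200, len(seq) - 200))
        if any(a <= p < b for a, b in taken):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        tsd = int(rng.integers(4, 17))
        polya = int(rng.integers(10, 41))
        l1_len = int(rng.integers(150, len(L1HS_CONSENSUS_3P) + 1))
        junction = p if strand == "+" else p + tsd
        flank = _flank_from(seq, junction, strand, landing + "A" * polya,
                            cfg.enzyme_sites, cfg.flank_window)
        if len(flank) < min_flank:
            continue
        out.append(PlantedInsertion(contig, p, strand, l1_len, polya, tsd,
                                    origin, cell_fraction, tuple(sample_scope)))
        taken.append((p - min_spacing, p + min_spacing))
    return out


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

@dataclass
class LibraryResult:
    """Per-sample read pairs plus the per-molecule manifest (ground truth)."""

    reads: dict[str, list[tuple[str, str, str, str, str]]]
    manifest: pd.DataFrame
    truth: TruthSet
    cfg: SimConfig


def _apply_substitutions(reads: list[str], rng: np.random.Generator,
                         rate: float) -> None:
    """In-place per-base substitution errors on a list of read strings."""
    if rate <= 0 or not reads:
        return
    lens = np.fromiter((len(r) for r in reads), dtype=np.int64, count=len(reads))
    counts = rng.binomial(lens, rate)
    for i in np.flatnonzero(counts):
        s = list(reads[i])
        for p in rng.integers(0, lens[i], counts[i]):
            s[p] = DNA_ALPHABET[(DNA_ALPHABET.index(s[p]) +
                                 int(rng.integers(1, 4))) % 4] if s[p] in DNA_ALPHABET else s[p]
        reads[i] = "".join(s)


def _pad(seq: str, read_len: int) -> str:
    # NextSeq-style: cycles past the template read as G (no-signal base)
    return seq[:read_len] if len(seq) >= read_len else seq + "G" * (read_len - len(seq))


def simulate_library(truth: TruthSet, ref: ReferenceAssembly,
                     cfg: SimConfig) -> LibraryResult:
    """Emit paired reads per sample following the stem-loop UMI architecture.

    For each sample, each locus present in that sample contributes
    Binomial(genome_equivalents, cell_fraction) original molecules; each
    molecule gets a fresh UMI and Poisson(mean_reads_per_molecule)
    duplicate read pairs.  A ``chimera_rate`` fraction of molecules has its
    genomic flank swapped for a random locus, modeling ligation/PCR
    artifacts.  Deterministic for a given (truth, cfg).
    """
    protocol = cfg.protocol()
    stem, read_len, umi_len = protocol.stem, cfg.read_len, cfg.umi_len
    loci = build_loci(ref, truth, cfg)
    if not any(l.flank for l in loci):
        logger.warning("no amplifiable fragments; emitting empty library")
    qual = "I" * read_len
    genome = {name: seq for name, seq in ref.contigs.items()}
    contig_names = sorted(genome)
    rc_stem = revcomp(stem)

    reads_by_sample: dict[str, list[tuple[str, str, str, str, str]]] = {}
    manifest_rows: list[tuple] = []
    for s_idx, sample in enumerate(truth.samples):
        rng = np.random.default_rng([cfg.seed, 2, s_idx])
        pairs: list[tuple[str, str, str, str, str]] = []
        seqs1: list[str] = []
        seqs2: list[str] = []
        ids: list[str] = []
        mol_serial = 0
        for loc in loci:
            if loc.sample_scope is not None and sample.sample_id not in loc.sample_scope:
                continue
            n_mol = int(rng.binomial(cfg.genome_equivalents, loc.cell_fraction))
            if n_mol == 0:
                continue
            umis = [decode(row) for row in
                    rng.integers(0, 4, (n_mol, umi_len), dtype=np.uint8)]
            dups = rng.poisson(cfg.mean_reads_per_molecule, n_mol)
            chim = rng.random(n_mol) < cfg.chimera_rate
            mol_plain = loc.molecule
            rc_plain = revcomp(mol_plain)
            r1_plain = _pad(mol_plain, read_len) if len(mol_plain) >= read_len else None
            for m in range(n_mol):
                mol_serial += 1
                if dups[m] == 0:
                    continue
                umi = umis[m]
                if chim[m]:
                    c = contig_names[int(rng.integers(0, len(contig_names)))]
                    pos = int(rng.integers(0, len(genome[c])))
                    cstrand = "+" if rng.random() < 0.5 else "-"
                    flank = _flank_from(genome[c], pos, cstrand, loc.head,
                                        cfg.enzyme_sites, cfg.flank_window)
                    mol = loc.head + flank
                    rc_mol = revcomp(mol)
                    r1 = _pad(mol + revcomp(umi) + rc_stem, read_len)
                else:
                    mol, rc_mol = mol_plain, rc_plain
                    r1 = (r1_plain if r1_plain is not None
                          else _pad(mol + revcomp(umi) + rc_stem, read_len))
                r2 = _pad(stem + umi + rc_mol, read_len)
                base_id = f"{sample.sample_id}:{mol_serial:07d}"
                for d in range(int(dups[m])):
                    ids.append(f"{base_id}:{d}")
                    seqs1.append(r1)
                    seqs2.append(r2)
                manifest_rows.append((sample.sample_id, base_id, loc.locus_id,
                                      loc.contig, loc.junction, loc.strand,
                                      loc.origin, umi, int(dups[m]), bool(chim[m])))
        _apply_substitutions(seqs1, rng, cfg.subst_error_rate)
        _apply_substitutions(seqs2, rng, cfg.subst_error_rate)
        pairs = [(i, s1, qual[:len(s1)], s2, qual[:len(s2)])
                 for i, s1, s2 in zip(ids, seqs1, seqs2)]
        reads_by_sample[sample.sample_id] = pairs
    manifest = pd.DataFrame(
        manifest_rows,
        columns=["sample_id", "molecule_id", "locus_id", "contig", "junction",
                 "strand", "origin", "umi", "n_reads", "chimera"])
    return LibraryResult(reads=reads_by_sample, manifest=manifest,
                         truth=truth, cfg=cfg)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_TRUTH_COLUMNS = ["contig", "target_pos", "strand", "l1_length", "polya_len",
                  "tsd_len", "origin", "cell_fraction", "sample_scope"]


def write_truth(truth: TruthSet, bed_path: str | Path, tsv_path: str | Path) -> None:
    """Write the truth set as BED6 (insertion points) + a full TSV.

    BED score encodes the cell fraction as round(10000 * fraction); the TSV
    header comments carry the seed and the sample sheet so a read-back
    reconstructs the in-memory truth exactly.
    """
    rows = sorted(truth.insertions, key=lambda i: (i.contig, i.target_pos))
    with open(bed_path, "w") as bed:
        for ins in rows:
            bed.write(f"{ins.contig}\t{ins.target_pos}\t{ins.target_pos + 1}\t"
                      f"{ins.origin}\t{round(10000 * ins.cell_fraction)}\t"
                      f"{ins.strand}\n")
    with open(tsv_path, "w") as tsv:
        tsv.write(f"#seed={truth.seed}\n")
        for s in truth.samples:
            tsv.write(f"#sample={s.sample_id}\t{s.subject}\t{s.timepoint}\t"
                      f"{s.condition}\n")
        tsv.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for ins in rows:
            tsv.write("\t".join(str(v) for v in (
                ins.contig, ins.target_pos, ins.strand, ins.l1_length,
                ins.polya_len, ins.tsd_len, ins.origin,
                repr(ins.cell_fraction), ",".join(ins.sample_scope))) + "\n")


def read_truth(tsv_path: str | Path) -> TruthSet:
    seed = 0
    samples: list[SampleSpec] = []
    insertions: list[PlantedInsertion] = []
    with open(tsv_path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#seed="):
                seed = int(line[len("#seed="):])
                continue
            if line.startswith("#sample="):
                sid, subject, timepoint, condition = line[len("#sample="):].split("\t")
                samples.append(SampleSpec(sid, subject, timepoint, condition))
                continue
            if header is None:
                header = line.split("\t")
                if header != _TRUTH_COLUMNS:
                    raise ValueError(f"unexpected truth TSV columns: {header}")
                continue
            if not line:
                continue
            f = line.split("\t")
            insertions.append(PlantedInsertion(
                contig=f[0], target_pos=int(f[1]), strand=f[2],
                l1_length=int(f[3]), polya_len=int(f[4]), tsd_len=int(f[5]),
                origin=f[6], cell_fraction=float(f[7]),
                sample_scope=tuple(x for x in f[8].split(",") if x)))
    return TruthSet(tuple(insertions), tuple(samples), seed)


def observed_breakpoint(ref: ReferenceAssembly, ins: PlantedInsertion,
                        polya_min_run: int = 5) -> int:
    """Junction coordinate the pipeline reports for a planted insertion.

    When the genomic flank itself starts with adenosines, the element's
    poly(A) tail and the flank are not separable in the read; the parser
    trims the maximal run, so the observed junction shifts past those
    bases.  This applies the same trimming rule to the reference sequence
    and returns the left-normalized coordinate the caller will emit.
    """
    from .ingest import _leading_polya

    seq = ref.contigs[ins.contig]
    bp = ins.breakpoint
    flank = seq[bp:bp + 200] if ins.strand == "+" else revcomp(seq[max(0, bp - 200):bp])
    run = _leading_polya("A" * ins.polya_len + flank, polya_min_run)
    shift = run - ins.polya_len
    return bp + shift if ins.strand == "+" else bp - shift


def write_reference(ref: ReferenceAssembly, fasta_path: str | Path,
                    catalogue_bed: str | Path | None = None) -> None:
    """Write the assembly as FASTA plus the L1 catalogue as BED6."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in ref.contigs.items()]
    SeqIO.write(records, str(fasta_path), "fasta")
    if catalogue_bed is not None:
        with open(catalogue_bed, "w") as bed:
            for i, c in enumerate(sorted(ref.l1_catalogue,
                                         key=lambda x: (x.contig, x.start))):
                score = 1000 if c.is_amplifiable else 0
                bed.write(f"{c.contig}\t{c.start}\t{c.end}\tL1HS_{i:03d}\t"
                          f"{score}\t{c.strand}\n")


def read_reference(fasta_path: str | Path,
                   catalogue_bed: str | Path | None = None) -> ReferenceAssembly:
    from Bio import SeqIO

    contigs = {rec.id: str(rec.seq).upper()
               for rec in SeqIO.parse(str(fasta_path), "fasta")}
    catalogue: list[RefL1Copy] = []
    if catalogue_bed is not None:
        with open(catalogue_bed) as bed:
            for line in bed:
                if not line.strip() or line.startswith("#"):
                    continue
                contig, start, end, _name, score, strand = line.split("\t")[:6]
                catalogue.append(RefL1Copy(contig, int(start), int(end),
                                           strand.strip(),
                                           int(score) > 0))
    ref = ReferenceAssembly(contigs=contigs, l1_catalogue=tuple(catalogue))
    ref.validate()
    return ref


def write_fastq_pair(pairs: Iterable[tuple[str, str, str, str, str]],
                     path1: str | Path, path2: str | Path) -> int:
    """Write (id, seq1, qual1, seq2, qual2) records as a FASTQ file pair."""
    n = 0
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for rid, s1, q1, s2, q2 in pairs:
            f1.write(f"@{rid}/1\n{s1}\n+\n{q1}\n")
            f2.write(f"@{rid}/2\n{s2}\n+\n{q2}\n")
            n += 1
    return n


def write_library(lib: LibraryResult, outdir: str | Path) -> dict[str, tuple[Path, Path]]:
    """Write per-sample FASTQ pairs and the molecule manifest under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, tuple[Path, Path]] = {}
    for sample_id, pairs in lib.reads.items():
        p1 = outdir / f"{sample_id}_R1.fastq"
        p2 = outdir / f"{sample_id}_R2.fastq"
        write_fastq_pair(pairs, p1, p2)
        paths[sample_id] = (p1, p2)
    lib.manifest.to_csv(outdir / "molecules.tsv", sep="\t", index=False)
    return paths
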