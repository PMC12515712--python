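"""Self-contained k-mer seed-and-extend flank aligner.

Sized for desk-scale genomes (a few Mb): the forward strand is indexed as
sorted 2-bit k-mer codes over a concatenated genome array, queries are
seeded on both orientations, seed hits vote for diagonals, and the best
diagonals are scored by ungapped extension (match +1 / mismatch -1).
Uniqueness is the score gap to the best alignment at any *other* locus.
No gapped alignment: amplicon flanks are short and indel-free by design.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .config import MapperParams
from .seqs import encode, revcomp

logger = logging.getLogger("l1trace.mapping")

__all__ = ["KmerIndex", "FlankAlignment", "build_index", "map_flank",
           "junction_of", "pair_concordance"]

_GAP = 32  # N-gap inserted between concatenated contigs


@dataclass(frozen=True)
class FlankAlignment:
    contig: str
    start: int       # 0-based half-open on the reference forward strand
    end: int
    strand: str
    identity: float
    score: int
    second_best_score: int
    unique: bool
    read_id: str = ""


@dataclass
class KmerIndex:
    k: int
    names: list[str]
    offsets: np.ndarray       # global start of each contig in genome_arr
    lengths: np.ndarray
    genome_arr: np.ndarray    # uint8 codes, contigs separated by N gaps
    codes_sorted: np.ndarray  # uint64 k-mer codes, sorted
    pos_sorted: np.ndarray    # global positions, parallel to codes_sorted

    @property
    def n_postings(self) -> int:
        return len(self.pos_sorted)

    def to_local(self, gpos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
        return self.names[i], gpos - int(self.offsets[i])


def _rolling_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, valid) for every k-window of a uint8 code array."""
    n = len(arr) - k + 1
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | (arr[j:j + n] & np.uint8(3)).astype(np.uint64)
    bad = (arr > 3).astype(np.int32)
    window_bad = np.convolve(bad, np.ones(k, dtype=np.int32), mode="valid")
    return codes, window_bad == 0


def build_index(ref, k: int = 15) -> KmerIndex:
    """Index the forward strand of every contig; deterministic.

    Contigs shorter than k are skipped with a warning.
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    names, seqs = [], []
    for name in ref.contigs:
        if len(ref.contigs[name]) < k:
            warnings.warn(f"contig {name} shorter than k={k}; skipped")
            continue
        names.append(name)
        seqs.append(ref.contigs[name])
    if not names:
        empty = np.array([], dtype=np.uint64)
        return KmerIndex(k, [], np.array([], dtype=np.int64),
                         np.array([], dtype=np.int64),
                         np.array([], dtype=np.uint8), empty,
                         np.array([], dtype=np.int64))
    offsets, parts, pos = [], [], 0
    for seq in seqs:
        offsets.append(pos)
        parts.append(encode(seq))
        pos += len(seq)
        parts.append(np.full(_GAP, 4, dtype=np.uint8))
        pos += _GAP
    genome_arr = np.concatenate(parts)
    codes, valid = _rolling_codes(genome_arr, k)
    idx = np.flatnonzero(valid)
    order = np.argsort(codes[idx], kind="stable")
    return KmerIndex(k, names, np.asarray(offsets, dtype=np.int64),
                     np.asarray([len(s) for s in seqs], dtype=np.int64),
                     genome_arr, codes[idx][order],
                     idx[order].astype(np.int64))


def _seed_codes(qarr: np.ndarray, offs: list[int], k: int
                ) -> tuple[np.ndarray, np.ndarray]:
    """uint64 codes for the k-windows at ``offs``, plus a validity mask."""
    windows = qarr[np.add.outer(np.asarray(offs), np.arange(k))]
    shifts = (np.uint64(2) * np.arange(k - 1, -1, -1, dtype=np.uint64))
    codes = ((windows & np.uint8(3)).astype(np.uint64) << shifts).sum(
        axis=1, dtype=np.uint64)
    return codes, (windows <= 3).all(axis=1)


def map_flank(flank: str, idx: KmerIndex,
              params: MapperParams = MapperParams()) -> FlankAlignment | None:
    """Best ungapped placement of a flank, or None if below min identity.

    Both orientations are tried; ``unique`` is set when the best score
    beats the best alignment at any other locus by the uniqueness margin.
    """
    L = len(flank)
    k = idx.k
    if L < k or idx.n_postings == 0:
        return None
    votes: dict[tuple[str, int], int] = {}
    queries = {"+": encode(flank), "-": encode(revcomp(flank))}
    n_off = max(1, min(params.n_seeds, L - k + 1))
    offs = sorted({int(o) for o in np.linspace(0, L - k, n_off)})
    for strand, qarr in queries.items():
        codes, valid = _seed_codes(qarr, offs, k)
        # keep the codes uint64: python ints would trigger a whole-array
        # type promotion inside searchsorted
        los = np.searchsorted(idx.codes_sorted, codes, side="left")
        his = np.searchsorted(idx.codes_sorted, codes, side="right")
        for off, ok, lo, hi in zip(offs, valid, los, his):
            if not ok or hi - lo > params.max_hits_per_seed:
                continue
            for gpos in idx.pos_sorted[lo:hi]:
                diag = int(gpos) - off
                key = (strand, diag)
                votes[key] = votes.get(key, 0) + 1
    if not votes:
        return None
    # deterministic candidate order: votes desc, then strand, then diagonal
    cands = sorted(votes, key=lambda c: (-votes[c], c[0], c[1]))
    cands = cands[:params.max_candidates]
    N = len(idx.genome_arr)
    scored: list[tuple[int, float, str, int]] = []
    for strand, diag in cands:
        if diag < 0 or diag + L > N:
            continue
        g = idx.genome_arr[diag:diag + L]
        q = queries[strand]
        mm = int(np.count_nonzero(g != q)) + int(np.count_nonzero((g == 4) & (q == 4)))
        scored.append((L - 2 * mm, (L - mm) / L, strand, diag))
    if not scored:
        return None
    scored.sort(key=lambda t: (-t[0], t[2], t[3]))
    best_score, best_id, best_strand, best_diag = scored[0]
    second = 0
    for sc, _ident, strand, diag in scored[1:]:
        if strand != best_strand or abs(diag - best_diag) > L:
            second = sc
            break
    if best_id < params.min_identity:
        return None
    contig, local = idx.to_local(best_diag)
    return FlankAlignment(contig=contig, start=local, end=local + L,
                          strand=best_strand, identity=best_id,
                          score=best_score, second_best_score=second,
                          unique=(best_score - second) >= params.uniqueness_margin)


def junction_of(aln: FlankAlignment) -> int:
    """Reference coordinate of the flank edge adjacent to the L1 element.

    The mapped flank is junction-anchored at its first (molecule-forward)
    base, so the junction is the alignment start on '+' and the alignment
    end on '-'.
    """
    return aln.start if aln.strand == "+" else aln.end


def pair_concordance(aln_primary: FlankAlignment,
                     aln_other: FlankAlignment | None,
                     max_span: int = 600) -> bool:
    """Do the two mates' flanks tell the same story?

    ``aln_other`` = None means the other mate's flank was uninformative
    (the read ended inside L1/poly(A)); by convention that is concordant.
    Otherwise both flanks must land on the same contig and strand within
    ``max_span`` nt.
    """
    if aln_other is None:
        return True
    return (aln_primary.contig == aln_other.contig
            and aln_primary.strand == aln_other.strand
            and abs(junction_of(aln_primary) - junction_of(aln_other)) <= max_span)
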