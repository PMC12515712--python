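"""Per-sample insertion calling: breakpoint clustering, UMI collapse,
known-copy annotation.

Mapped junction flanks from one sample are single-linkage clustered along
each contig; each cluster's UMIs are collapsed into molecule counts
(connected components under a small Hamming radius, absorbing sequencing
errors in the UMI), and clusters are annotated against the catalogue of
reference L1 copies so known population loci can be excluded downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulate import RefL1Copy, SampleSpec

logger = logging.getLogger("l1trace.calling")

__all__ = ["MappedRead", "InsertionCluster", "SampleCallSet",
           "cluster_breakpoints", "collapse_umis", "annotate_reference_l1",
           "build_callset", "callset_to_frame", "write_callset"]


@dataclass(frozen=True)
class MappedRead:
    """One pass-status read reduced to its junction evidence."""
    read_id: str
    contig: str
    breakpoint: int
    strand: str
    umi: str
    concordant: bool


@dataclass(frozen=True)
class InsertionCluster:
    sample_id: str
    contig: str
    breakpoint: int
    strand: str
    read_count: int
    umi_count: int
    umis: tuple[str, ...]
    concordant_fraction: float
    is_known_l1: bool = False


@dataclass(frozen=True)
class SampleCallSet:
    sample_id: str
    subject: str
    timepoint: str
    condition: str
    clusters: tuple[InsertionCluster, ...]


def collapse_umis(umis: Sequence[str], max_hamming: int = 1) -> int:
    """Number of original molecules: connected components of the UMI graph.

    Two UMIs are linked when their Hamming distance is <= ``max_hamming``;
    sequencing errors in the UMI then do not inflate molecule counts.
    Mixed UMI lengths are an input error.
    """
    if not umis:
        return 0
    uniq = sorted(set(umis))
    lengths = {len(u) for u in uniq}
    if len(lengths) != 1:
        raise ValueError(f"mixed UMI lengths: {sorted(lengths)}")
    m = len(uniq)
    if max_hamming == 0 or m == 1:
        return m
    L = lengths.pop()
    parent = list(range(m))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    if max_hamming == 1:
        # exact linear-time linking: u and v are within Hamming 1 iff they
        # are identical after deleting some one position
        groups: dict[tuple[int, str], int] = {}
        for i, u in enumerate(uniq):
            for p in range(L):
                j = groups.setdefault((p, u[:p] + u[p + 1:]), i)
                if j != i:
                    union(i, j)
    else:
        arr = np.frombuffer("".join(uniq).encode("ascii"),
                            dtype=np.uint8).reshape(m, L)
        chunk = 512
        for lo in range(0, m, chunk):
            block = arr[lo:lo + chunk]
            # pairwise Hamming distances, chunked to bound memory
            d = (block[:, None, :] != arr[None, :, :]).sum(axis=2)
            ii, jj = np.nonzero(d <= max_hamming)
            for i, j in zip(ii, jj):
                if int(j) > int(i) + lo:
                    union(int(i) + lo, int(j))
    return len({find(i) for i in range(m)})


def _lower_median(values: Sequence[int]) -> int:
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def cluster_breakpoints(reads: Iterable[MappedRead], window: int = 15,
                        sample_id: str = "",
                        umi_max_hamming: int = 1) -> list[InsertionCluster]:
    """Single-linkage clustering of junction coordinates within ``window``.

    Cluster breakpoint is the (lower) median member coordinate; strand is
    the member majority with ties resolved toward '+'.  Invariant to the
    input order.
    """
    by_contig: dict[str, list[MappedRead]] = {}
    for r in reads:
        by_contig.setdefault(r.contig, []).append(r)
    clusters: list[InsertionCluster] = []
    for contig in sorted(by_contig):
        members = sorted(by_contig[contig],
                         key=lambda r: (r.breakpoint, r.read_id))
        group: list[MappedRead] = []
        for r in members:
            if group and r.breakpoint - group[-1].breakpoint > window:
                clusters.append(_finalize(group, sample_id, umi_max_hamming))
                group = []
            group.append(r)
        if group:
            clusters.append(_finalize(group, sample_id, umi_max_hamming))
    clusters.sort(key=lambda c: (c.contig, c.breakpoint))
    return clusters


def _finalize(group: list[MappedRead], sample_id: str,
              umi_max_hamming: int) -> InsertionCluster:
    n_plus = sum(1 for r in group if r.strand == "+")
    strand = "+" if n_plus * 2 >= len(group) else "-"
    umis = tuple(sorted(r.umi for r in group))
    return InsertionCluster(
        sample_id=sample_id,
        contig=group[0].contig,
        breakpoint=_lower_median([r.breakpoint for r in group]),
        strand=strand,
        read_count=len(group),
        umi_count=collapse_umis(umis, umi_max_hamming),
        umis=umis,
        concordant_fraction=sum(r.concordant for r in group) / len(group),
    )


def annotate_reference_l1(clusters: Sequence[InsertionCluster],
                          catalogue: Sequence[RefL1Copy],
                          margin: int = 100,
                          amplifiable_only: bool = True,
                          ) -> list[InsertionCluster]:
    """Flag clusters whose breakpoint sits near a catalogued L1 3' end.

    A cluster is a known population locus when its breakpoint lies within
    ``margin`` nt of the 3' junction of a catalogued (by default
    amplifiable) copy.
    """
    junctions: dict[str, np.ndarray] = {}
    for copy in catalogue:
        if amplifiable_only and not copy.is_amplifiable:
            continue
        junctions.setdefault(copy.contig, [])
        junctions[copy.contig].append(copy.junction)
    junctions = {c: np.sort(np.asarray(v, dtype=np.int64))
                 for c, v in junctions.items()}
    out = []
    for cl in clusters:
        known = False
        pos = junctions.get(cl.contig)
        if pos is not None and len(pos):
            i = int(np.searchsorted(pos, cl.breakpoint))
            near = min(
                (abs(cl.breakpoint - int(pos[j]))
                 for j in (i - 1, i) if 0 <= j < len(pos)),
                default=margin + 1)
            known = near <= margin
        out.append(replace(cl, is_known_l1=known))
    return out


def build_callset(sample: SampleSpec,
                  clusters: Sequence[InsertionCluster]) -> SampleCallSet:
    clusters = tuple(sorted((replace(c, sample_id=sample.sample_id)
                             for c in clusters),
                            key=lambda c: (c.contig, c.breakpoint)))
    return SampleCallSet(sample.sample_id, sample.subject, sample.timepoint,
                         sample.condition, clusters)


def callset_to_frame(cs: SampleCallSet) -> pd.DataFrame:
    """BED6+-style table: locus, evidence and known-copy flag per cluster."""
    return pd.DataFrame(
        [(c.contig, c.breakpoint, c.breakpoint + 1, cs.sample_id, 0, c.strand,
          c.read_count, c.umi_count, round(c.concordant_fraction, 4),
          int(c.is_known_l1)) for c in cs.clusters],
        columns=["contig", "start", "end", "name", "score", "strand",
                 "read_count", "umi_count", "concordant_fraction",
                 "is_known_l1"])


def write_callset(cs: SampleCallSet, path: str | Path,
                  header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        callset_to_frame(cs).to_csv(fh, sep="\t", index=False)
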