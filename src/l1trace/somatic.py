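"""Candidate-selection cascade for somatic L1 insertions.

Follow-up callsets are compared with their subject's baseline (serial
samples share clonal and germline insertions, so any locus present at
baseline is subtracted); loci recurring in a *different* treatment arm of
the same line are excluded as library artifacts (independent insertions
into the same locus in different cells are vanishingly unlikely); known
population L1 copies are excluded; and the remaining loci must clear the
assay's evidence thresholds — read support strictly greater than 10,
at least 2 distinct molecules (UMIs), and mate concordance.  Rejected
records are retained with the first failing filter so the whole funnel is
auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import FilterConfig
from .calling import InsertionCluster, SampleCallSet

logger = logging.getLogger("l1trace.somatic")

__all__ = ["CandidateInsertion", "subtract_baseline", "cross_condition_exclude",
           "apply_evidence_filters", "compare_serial_samples", "RunReport",
           "summarize_run", "write_context_fasta"]

# evaluation order determines which failing filter is reported first
_FILTER_ORDER = ("cross_condition", "known_l1", "reads", "umis", "concordance")


@dataclass(frozen=True)
class CandidateInsertion:
    contig: str
    breakpoint: int
    strand: str
    sample_id: str
    read_count: int
    umi_count: int
    concordant_fraction: float
    is_known_l1: bool
    filter_flags: dict = field(default_factory=dict)
    status: str = "pending"     # pending | candidate | rejected

    @property
    def fail_reason(self) -> str:
        for name in _FILTER_ORDER:
            if self.filter_flags.get(name) is False:
                return name
        return ""


def _sorted_breakpoints(cs: SampleCallSet) -> dict[str, np.ndarray]:
    by_contig: dict[str, list[int]] = {}
    for c in cs.clusters:
        by_contig.setdefault(c.contig, []).append(c.breakpoint)
    return {k: np.sort(np.asarray(v, dtype=np.int64))
            for k, v in by_contig.items()}


def _has_match(index: dict[str, np.ndarray], contig: str, pos: int,
               window: int) -> bool:
    arr = index.get(contig)
    if arr is None or not len(arr):
        return False
    i = int(np.searchsorted(arr, pos))
    for j in (i - 1, i):
        if 0 <= j < len(arr) and abs(pos - int(arr[j])) <= window:
            return True
    return False


def _as_candidate(cl: InsertionCluster) -> CandidateInsertion:
    return CandidateInsertion(cl.contig, cl.breakpoint, cl.strand,
                              cl.sample_id, cl.read_count, cl.umi_count,
                              cl.concordant_fraction, cl.is_known_l1)


def subtract_baseline(followup: SampleCallSet, baseline: SampleCallSet,
                      cfg: FilterConfig = FilterConfig()
                      ) -> list[CandidateInsertion]:
    """Follow-up clusters with no baseline cluster within the match window.

    Matching is symmetric in the window and strand-agnostic: a breakpoint
    present at baseline, whatever its orientation call, marks the locus as
    pre-existing.  Comparing a callset against itself yields nothing.
    """
    if followup.subject != baseline.subject:
        raise ValueError(
            f"cannot pair {followup.sample_id} (subject {followup.subject}) "
            f"with baseline {baseline.sample_id} (subject {baseline.subject})")
    base = _sorted_breakpoints(baseline)
    return [_as_candidate(c) for c in followup.clusters
            if not _has_match(base, c.contig, c.breakpoint, cfg.match_window)]


def cross_condition_exclude(candidates: Sequence[CandidateInsertion],
                            other_callsets: Sequence[SampleCallSet],
                            cfg: FilterConfig = FilterConfig(),
                            condition: str | None = None,
                            ) -> list[CandidateInsertion]:
    """Flag candidates recurring in a different treatment arm.

    ``other_callsets`` should be the callsets of the same subject;
    callsets whose condition equals ``condition`` (the candidates' own
    arm) are ignored, so for a single-arm design this is the identity.
    Flags are recorded; nothing is dropped.
    """
    indexes = [_sorted_breakpoints(cs) for cs in other_callsets
               if condition is None or cs.condition != condition]
    out = []
    for cand in candidates:
        matched = any(_has_match(ix, cand.contig, cand.breakpoint,
                                 cfg.match_window) for ix in indexes)
        flags = dict(cand.filter_flags)
        flags["cross_condition"] = not matched
        out.append(replace(cand, filter_flags=flags))
    return out


def apply_evidence_filters(candidates: Sequence[CandidateInsertion],
                           cfg: FilterConfig = FilterConfig()
                           ) -> list[CandidateInsertion]:
    """Set per-filter flags and final status.

    Read support must be strictly greater than ``min_reads_exclusive``
    (the assay's ">10" rule) while UMI support is inclusive
    (">= min_umis", the "(>=2)" rule).  A record is a candidate iff every
    flag (including any upstream cross-condition flag) passes.
    """
    out = []
    for cand in candidates:
        flags = dict(cand.filter_flags)
        flags["known_l1"] = (not cand.is_known_l1) or not cfg.exclude_known_l1
        flags["reads"] = cand.read_count > cfg.min_reads_exclusive
        flags["umis"] = cand.umi_count >= cfg.min_umis
        flags["concordance"] = (cand.concordant_fraction
                                >= cfg.min_concordant_fraction)
        status = "candidate" if all(flags.values()) else "rejected"
        out.append(replace(cand, filter_flags=flags, status=status))
    return out


def compare_serial_samples(callsets: Sequence[SampleCallSet],
                           baseline_label: str,
                           cfg: FilterConfig = FilterConfig()
                           ) -> dict[str, list[CandidateInsertion]]:
    """Run the full cascade for every follow-up sample of every subject.

    The baseline of a subject+condition arm is the callset whose timepoint
    equals ``baseline_label``; every other callset of that arm is compared
    against it, then cross-checked against the subject's other arms.
    Results are keyed by follow-up sample id and independent of input
    order.
    """
    ordered = sorted(callsets, key=lambda c: c.sample_id)
    results: dict[str, list[CandidateInsertion]] = {}
    subjects = sorted({c.subject for c in ordered})
    for subject in subjects:
        mine = [c for c in ordered if c.subject == subject]
        for arm in sorted({c.condition for c in mine}):
            arm_sets = [c for c in mine if c.condition == arm]
            baselines = [c for c in arm_sets if c.timepoint == baseline_label]
            if len(baselines) != 1:
                raise ValueError(
                    f"subject {subject}, condition {arm}: expected exactly one "
                    f"baseline (timepoint={baseline_label!r}), "
                    f"found {len(baselines)}")
            baseline = baselines[0]
            others = [c for c in mine if c.condition != arm]
            for fu in arm_sets:
                if fu.sample_id == baseline.sample_id:
                    continue
                cands = subtract_baseline(fu, baseline, cfg)
                cands = cross_condition_exclude(cands, others, cfg,
                                                condition=arm)
                results[fu.sample_id] = apply_evidence_filters(cands, cfg)
    return results


@dataclass
class RunReport:
    per_sample: pd.DataFrame
    candidates: pd.DataFrame

    def log_funnel(self) -> str:
        lines = []
        for _, row in self.per_sample.iterrows():
            lines.append(
                f"{row['sample_id']}: {row['clusters_total']} clusters -> "
                f"{row['after_baseline']} after baseline subtraction -> "
                f"{row['final_candidates']} candidates "
                f"(known-L1 {row['rejected_known_l1']}, cross-condition "
                f"{row['rejected_cross_condition']}, reads {row['rejected_reads']}, "
                f"UMIs {row['rejected_umis']}, concordance "
                f"{row['rejected_concordance']})")
        text = "\n".join(lines)
        logger.info("somatic filter funnel:\n%s", text)
        return text


def summarize_run(callsets: Sequence[SampleCallSet],
                  results: dict[str, list[CandidateInsertion]]) -> RunReport:
    """Per-sample funnel table plus the final candidate list.

    Conservation holds by construction: for every follow-up sample,
    clusters_total = baseline_matched + final_candidates + per-filter
    rejections (a record is attributed to its first failing filter).
    """
    by_id = {cs.sample_id: cs for cs in callsets}
    rows = []
    cand_rows = []
    for sample_id in sorted(results):
        cs = by_id[sample_id]
        cands = results[sample_id]
        n_total = len(cs.clusters)
        n_after_base = len(cands)
        reasons = {f"rejected_{name}": 0 for name in _FILTER_ORDER}
        n_final = 0
        for cand in cands:
            if cand.status == "candidate":
                n_final += 1
                cand_rows.append((cand.sample_id, cand.contig, cand.breakpoint,
                                  cand.strand, cand.read_count, cand.umi_count,
                                  round(cand.concordant_fraction, 4)))
            else:
                reasons[f"rejected_{cand.fail_reason}"] += 1
        rows.append({
            "sample_id": sample_id,
            "subject": cs.subject,
            "timepoint": cs.timepoint,
            "condition": cs.condition,
            "clusters_total": n_total,
            "known_l1": sum(c.is_known_l1 for c in cs.clusters),
            "baseline_matched": n_total - n_after_base,
            "after_baseline": n_after_base,
            **reasons,
            "final_candidates": n_final,
        })
    per_sample = pd.DataFrame(rows)
    candidates = pd.DataFrame(
        cand_rows, columns=["sample_id", "contig", "breakpoint", "strand",
                            "read_count", "umi_count", "concordant_fraction"])
    return RunReport(per_sample=per_sample, candidates=candidates)


def write_context_fasta(candidates: pd.DataFrame, ref, path: str | Path,
                        pad: int = 250) -> None:
    """Reference context (±pad nt) around each candidate, for primer design."""
    with open(path, "w") as fh:
        for _, row in candidates.iterrows():
            seq = ref.contigs[row["contig"]]
            lo = max(0, int(row["breakpoint"]) - pad)
            hi = min(len(seq), int(row["breakpoint"]) + pad)
            fh.write(f">{row['sample_id']}|{row['contig']}:{lo}-{hi}|"
                     f"bp={row['breakpoint']}\n{seq[lo:hi]}\n")
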