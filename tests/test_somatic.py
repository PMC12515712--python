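"""Somatic filter cascade: baseline subtraction, cross-condition
exclusion, evidence thresholds, funnel reporting."""

from __future__ import annotations

import dataclasses
import random

import pytest

from l1trace.config import FilterConfig
from l1trace.calling import InsertionCluster, SampleCallSet
from l1trace.somatic import (apply_evidence_filters, compare_serial_samples,
                             cross_condition_exclude, subtract_baseline,
                             summarize_run)

CFG = FilterConfig()


def _cluster(bp, sample="s", reads=20, umis=5, conc=1.0, known=False,
             strand="+", contig="chr1"):
    return InsertionCluster(sample, contig, bp, strand, reads, umis,
                            ("AAAAAAAA",) * min(umis, 1), conc, known)


def _callset(breakpoints, sample="s", subject="subj", timepoint="followup",
             condition="arm1", **kw):
    clusters = tuple(sorted((_cluster(bp, sample, **kw)
                             for bp in breakpoints),
                            key=lambda c: (c.contig, c.breakpoint)))
    return SampleCallSet(sample, subject, timepoint, condition, clusters)


# ---------------------------------------------------------------------------
# baseline subtraction
# ---------------------------------------------------------------------------

def test_subtract_within_window_removed():
    fu = _callset([1000], "fu")
    base = _callset([1003], "base", timepoint="baseline")
    assert subtract_baseline(fu, base, CFG) == []


def test_subtract_outside_window_retained():
    fu = _callset([1000], "fu")
    base = _callset([1050], "base", timepoint="baseline")
    out = subtract_baseline(fu, base, CFG)
    assert [c.breakpoint for c in out] == [1000]


def test_subtract_strand_agnostic():
    fu = _callset([1000], "fu", strand="+")
    base = _callset([1000], "base", timepoint="baseline", strand="-")
    assert subtract_baseline(fu, base, CFG) == []


def test_self_subtraction_nullity():
    cs = _callset([100, 5000, 99_000])
    assert subtract_baseline(cs, cs, CFG) == []


def test_subtract_subject_mismatch_raises():
    fu = _callset([1000], subject="A")
    base = _callset([2000], subject="B")
    with pytest.raises(ValueError, match="subject"):
        subtract_baseline(fu, base, CFG)


# ---------------------------------------------------------------------------
# cross-condition exclusion
# ---------------------------------------------------------------------------

def test_cross_condition_flags_shared_locus():
    cands = subtract_baseline(_callset([1000], "fu", condition="arm1"),
                              _callset([], "base", timepoint="baseline",
                                       condition="arm1"), CFG)
    other = _callset([1010], "o", condition="arm2")
    out = cross_condition_exclude(cands, [other], CFG, condition="arm1")
    assert out[0].filter_flags["cross_condition"] is False
    final = apply_evidence_filters(out, CFG)
    assert final[0].status == "rejected"
    assert final[0].fail_reason == "cross_condition"


def test_cross_condition_ignores_same_arm():
    cands = subtract_baseline(_callset([1000], "fu", condition="arm1"),
                              _callset([], "base", timepoint="baseline",
                                       condition="arm1"), CFG)
    same_arm = _callset([1000], "o", condition="arm1")
    out = cross_condition_exclude(cands, [same_arm], CFG, condition="arm1")
    assert out[0].filter_flags["cross_condition"] is True


def test_cross_condition_single_arm_identity():
    cands = subtract_baseline(_callset([1000], "fu"),
                              _callset([], "base", timepoint="baseline"), CFG)
    out = cross_condition_exclude(cands, [], CFG, condition="arm1")
    assert out[0].filter_flags["cross_condition"] is True
    assert apply_evidence_filters(out, CFG)[0].status == "candidate"


# ---------------------------------------------------------------------------
# evidence thresholds
# ---------------------------------------------------------------------------

def _statuses(spec):
    cands = subtract_baseline(
        SampleCallSet("fu", "subj", "followup", "arm",
                      tuple(_cluster(1000 + 100 * i, "fu", reads=r, umis=u)
                            for i, (r, u) in enumerate(spec))),
        _callset([], "base", timepoint="baseline"), CFG)
    return apply_evidence_filters(cands, CFG)


def test_threshold_semantics_strict_and_inclusive():
    out = _statuses([(10, 2), (11, 1), (11, 2)])
    by = {(c.read_count, c.umi_count): c for c in out}
    assert by[(10, 2)].status == "rejected"
    assert by[(10, 2)].fail_reason == "reads"   # ">10" is strict
    assert by[(11, 1)].status == "rejected"
    assert by[(11, 1)].fail_reason == "umis"    # ">=2" is inclusive
    assert by[(11, 2)].status == "candidate"
    assert sum(c.status == "candidate" for c in out) == 1


def test_concordance_filter():
    cands = subtract_baseline(_callset([1000], "fu", conc=0.4),
                              _callset([], "base", timepoint="baseline"), CFG)
    out = apply_evidence_filters(cands, CFG)
    assert out[0].status == "rejected" and out[0].fail_reason == "concordance"


def test_known_l1_filter():
    cands = subtract_baseline(_callset([1000], "fu", known=True),
                              _callset([], "base", timepoint="baseline"), CFG)
    out = apply_evidence_filters(cands, CFG)
    assert out[0].status == "rejected" and out[0].fail_reason == "known_l1"
    relaxed = dataclasses.replace(CFG, exclude_known_l1=False)
    assert apply_evidence_filters(cands, relaxed)[0].status == "candidate"


def _random_callset(rng, sample="fu", subject="subj", timepoint="followup",
                    condition="arm1"):
    n = rng.randrange(0, 30)
    positions = sorted(rng.sample(range(0, 500_000, 50), n))
    clusters = tuple(
        _cluster(p, sample, reads=rng.randrange(1, 40),
                 umis=rng.randrange(1, 10), conc=rng.random(),
                 known=rng.random() < 0.2)
        for p in positions)
    return SampleCallSet(sample, subject, timepoint, condition, clusters)


def test_monotonicity_and_self_subtraction_randomized():
    rng = random.Random(99)
    for _ in range(60):
        cs = _random_callset(rng)
        assert subtract_baseline(cs, cs, CFG) == []
        base = _random_callset(rng, "base", timepoint="baseline")
        cands = subtract_baseline(cs, base, CFG)
        n0 = sum(c.status == "candidate"
                 for c in apply_evidence_filters(cands, CFG))
        for tightened in (
                dataclasses.replace(CFG, min_reads_exclusive=CFG.min_reads_exclusive + 5),
                dataclasses.replace(CFG, min_umis=CFG.min_umis + 2),
                dataclasses.replace(CFG, min_concordant_fraction=0.9),
                dataclasses.replace(CFG, match_window=CFG.match_window + 100)):
            cands_t = subtract_baseline(cs, base, tightened)
            n1 = sum(c.status == "candidate"
                     for c in apply_evidence_filters(cands_t, tightened))
            assert n1 <= n0


# ---------------------------------------------------------------------------
# serial comparison + report
# ---------------------------------------------------------------------------

def _cohort(rng):
    sets = []
    for subject in ("p1", "p2"):
        for cond in ("arm1", "arm2"):
            sets.append(_random_callset(rng, f"{subject}_{cond}_base",
                                        subject, "baseline", cond))
            sets.append(_random_callset(rng, f"{subject}_{cond}_fu",
                                        subject, "followup", cond))
    return sets


def test_compare_requires_exactly_one_baseline():
    fu = _callset([1000], "fu")
    with pytest.raises(ValueError, match="exactly one baseline"):
        compare_serial_samples([fu], "baseline", CFG)


def test_compare_order_invariance():
    rng = random.Random(7)
    sets = _cohort(rng)
    ref = compare_serial_samples(sets, "baseline", CFG)
    shuffled = list(sets)
    random.Random(1).shuffle(shuffled)
    assert compare_serial_samples(shuffled, "baseline", CFG) == ref


def test_report_conservation():
    rng = random.Random(21)
    sets = _cohort(rng)
    results = compare_serial_samples(sets, "baseline", CFG)
    report = summarize_run(sets, results)
    for _, row in report.per_sample.iterrows():
        rejected = sum(row[c] for c in row.index
                       if str(c).startswith("rejected_"))
        assert (row["clusters_total"]
                == row["baseline_matched"] + row["final_candidates"] + rejected)
    text = report.log_funnel()
    assert "candidates" in text


def test_report_candidates_columns():
    rng = random.Random(22)
    sets = _cohort(rng)
    report = summarize_run(sets, compare_serial_samples(sets, "baseline", CFG))
    assert list(report.candidates.columns) == [
        "sample_id", "contig", "breakpoint", "strand", "read_count",
        "umi_count", "concordant_fraction"]
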