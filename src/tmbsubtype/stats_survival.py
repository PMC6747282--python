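"""Subtype association statistics and disease-free-survival comparison.

Fisher exact tests (gene x subtype, clinical feature x subtype) with
Benjamini–Hochberg adjustment, Wilcoxon rank-sum comparisons of TMB, the
Kaplan–Meier product-limit estimator, and the two-group log-rank test.
All 2x2 tests are two-sided; only the permutation enrichment module is
one-tailed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_cohort import (
    AgeGroup,
    ClinicalRecord,
    Metastasis,
    Smoking,
    Stage,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p: float
    q: float | None = None
    table: tuple[tuple[int, int], tuple[int, int]] | None = None
    group_sizes: tuple[int, ...] | None = None
    degenerate: bool = False


@dataclass(frozen=True)
class SurvivalCurve:
    group: str
    times: tuple[float, ...]  # sorted distinct observed times
    at_risk: tuple[int, ...]
    survival: tuple[float, ...]  # S(t) at each time, non-increasing

    def survival_at(self, t: float) -> float:
        s = 1.0
        for time, surv in zip(self.times, self.survival):
            if time <= t:
                s = surv
            else:
                break
        return s


# ---------------------------------------------------------------------------
# Core tests


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table of nonnegative counts.

    p sums hypergeometric probabilities of tables at most as probable as the
    observed one.  A table with an all-zero margin yields p = 1 by
    convention (flagged degenerate).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 nonnegative integers")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        logger.info("fisher_exact_2x2: degenerate margin, p=1 by convention")
        return TestResult(
            "fisher_exact", statistic=np.nan, p=1.0,
            table=tuple(map(tuple, t)), degenerate=True,
        )
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(
        "fisher_exact", statistic=float(odds), p=float(p), table=tuple(map(tuple, t))
    )


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon rank-sum of two groups; returns (rank-sum of x, p).

    Exact enumeration when both groups have <= 10 observations and there are
    no ties; otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 10 and y.size <= 10 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    w = float(res.statistic + x.size * (x.size + 1) / 2)  # U -> rank-sum of x
    return w, float(res.pvalue)


# ---------------------------------------------------------------------------
# Association batteries


def gene_subtype_association(
    mutation_matrix, subtypes, gene_list: Sequence[str] | None = None
) -> list[TestResult]:
    """Per-gene 2x2 Fisher test of mutation status vs subtype, BH-adjusted.

    The 2x2 is [[mut & H, mut & L], [wt & H, wt & L]]; q-values are computed
    across the supplied gene list (defaults to every matrix row).
    """
    from .subtyping import Subtype

    genes = list(gene_list) if gene_list is not None else list(mutation_matrix.genes)
    gene_ix = {g: i for i, g in enumerate(mutation_matrix.genes)}
    missing = [g for g in genes if g not in gene_ix]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing[:5]}")
    label_by_sample = dict(zip(subtypes.sample_ids, subtypes.labels))
    is_high = np.array(
        [label_by_sample[s] is Subtype.TMB_H for s in mutation_matrix.samples]
    )
    results = []
    for g in genes:
        mut = mutation_matrix.data[gene_ix[g]].astype(bool)
        tab = [
            [int((mut & is_high).sum()), int((mut & ~is_high).sum())],
            [int((~mut & is_high).sum()), int((~mut & ~is_high).sum())],
        ]
        r = fisher_exact_2x2(tab)
        results.append(TestResult(
            f"fisher[{g}]~subtype", r.statistic, r.p, table=r.table,
            degenerate=r.degenerate,
        ))
    q = bh_adjust([r.p for r in results])
    return [
        TestResult(r.test_name, r.statistic, r.p, q=float(qi), table=r.table,
                   degenerate=r.degenerate)
        for r, qi in zip(results, q)
    ]


def tmb_by_mutation(tmb_profile, mutation_matrix, gene: str) -> TestResult:
    """Two-sided Wilcoxon rank-sum of TMB in mutant vs wild-type samples."""
    gene_ix = {g: i for i, g in enumerate(mutation_matrix.genes)}
    if gene not in gene_ix:
        raise ValueError(f"gene {gene!r} absent from matrix")
    tmb_by_sample = dict(zip(tmb_profile.sample_ids, tmb_profile.tmb))
    mut_row = mutation_matrix.data[gene_ix[gene]].astype(bool)
    mut = [tmb_by_sample[s] for s, m in zip(mutation_matrix.samples, mut_row) if m]
    wt = [tmb_by_sample[s] for s, m in zip(mutation_matrix.samples, mut_row) if not m]
    if not mut or not wt:
        raise ValueError(f"gene {gene!r}: mutant or wild-type group is empty")
    stat, p = wilcoxon_rank_sum(mut, wt)
    return TestResult(
        f"wilcoxon[TMB]~{gene}", stat, p, group_sizes=(len(mut), len(wt))
    )


_FEATURE_LEVELS = {
    "age_group": (AgeGroup.AT_LEAST65, AgeGroup.UNDER65, lambda c: c.age_group),
    "smoking": (Smoking.SMOKER, Smoking.NON_SMOKER, lambda c: c.smoking),
    "stage": (Stage.LATE, Stage.EARLY, lambda c: c.stage),
    "metastasis": (Metastasis.YES, Metastasis.NO, lambda c: c.metastasis),
}


def clinical_association(
    clinical: Sequence[ClinicalRecord], subtypes, feature: str, tmb_profile=None
) -> dict[str, TestResult]:
    """Associate a clinical feature with subtype (Fisher) and with raw TMB.

    Unknown/missing feature levels are excluded pairwise.  Returns a dict
    with key ``"fisher"`` and, when a TMB profile is supplied, key
    ``"tmb_wilcoxon"`` comparing raw TMB across the two feature levels.
    """
    from .subtyping import Subtype

    if feature not in _FEATURE_LEVELS:
        raise ValueError(f"feature must be one of {sorted(_FEATURE_LEVELS)}")
    pos_level, neg_level, getter = _FEATURE_LEVELS[feature]
    label_by_sample = dict(zip(subtypes.sample_ids, subtypes.labels))

    known = [
        c for c in clinical
        if getter(c) in (pos_level, neg_level) and c.sample_id in label_by_sample
    ]
    tab = [[0, 0], [0, 0]]
    for c in known:
        i = 0 if getter(c) == pos_level else 1
        j = 0 if label_by_sample[c.sample_id] is Subtype.TMB_H else 1
        tab[i][j] += 1
    fisher = fisher_exact_2x2(tab)
    degenerate = fisher.degenerate or any(sum(row) == 0 for row in tab)
    out = {
        "fisher": TestResult(
            f"fisher[{feature}]~subtype", fisher.statistic, fisher.p,
            table=fisher.table, degenerate=degenerate,
        )
    }
    if tmb_profile is not None:
        tmb_by_sample = dict(zip(tmb_profile.sample_ids, tmb_profile.tmb))
        pos = [tmb_by_sample[c.sample_id] for c in known if getter(c) == pos_level]
        neg = [tmb_by_sample[c.sample_id] for c in known if getter(c) == neg_level]
        if pos and neg:
            stat, p = wilcoxon_rank_sum(pos, neg)
            out["tmb_wilcoxon"] = TestResult(
                f"wilcoxon[TMB]~{feature}", stat, p,
                group_sizes=(len(pos), len(neg)),
            )
        else:
            out["tmb_wilcoxon"] = TestResult(
                f"wilcoxon[TMB]~{feature}", np.nan, 1.0, degenerate=True
            )
    return out


# ---------------------------------------------------------------------------
# Survival


def km_estimate(
    times: Sequence[float],
    events: Sequence[bool],
    group_labels: Sequence[str],
) -> dict[str, SurvivalCurve]:
    """Kaplan–Meier product-limit curves, one per group label."""
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(group_labels)
    if times.size == 0:
        raise ValueError("no subjects supplied")
    if (times < 0).any():
        raise ValueError("times must be nonnegative")
    out: dict[str, SurvivalCurve] = {}
    for g in pd.unique(groups):
        mask = groups == g
        if not mask.any():
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(g))
        tab = kmf.event_table
        surv = kmf.survival_function_[str(g)]
        t = [float(x) for x in tab.index if x > 0]
        out[str(g)] = SurvivalCurve(
            group=str(g),
            times=tuple(t),
            at_risk=tuple(int(tab.loc[x, "at_risk"]) for x in t),
            survival=tuple(float(surv.loc[x]) for x in t),
        )
    return out


def logrank_test(
    times: Sequence[float],
    events: Sequence[bool],
    group_labels: Sequence[str],
) -> TestResult:
    """Two-group log-rank chi-square test (1 df), two-sided.

    With no observed events at all the statistic is undefined; p = 1 is
    returned flagged degenerate.
    """
    from lifelines.statistics import logrank_test as _ll_logrank

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(group_labels)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {len(levels)}")
    m0, m1 = groups == levels[0], groups == levels[1]
    if not m0.any() or not m1.any():
        raise ValueError("both groups must be non-empty")
    if not events.any():
        return TestResult("logrank", 0.0, 1.0, group_sizes=(int(m0.sum()), int(m1.sum())),
                          degenerate=True)
    res = _ll_logrank(times[m0], times[m1], events[m0], events[m1])
    return TestResult(
        "logrank",
        float(res.test_statistic),
        float(res.p_value),
        group_sizes=(int(m0.sum()), int(m1.sum())),
    )
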