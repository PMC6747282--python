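"""Mutational-signature extraction from 96-context SNV counts.

SNVs with trinucleotide contexts are folded onto the pyrimidine strand and
tallied into the 96 substitution-by-flank categories.  Signatures are
extracted by nonnegative matrix factorization under a Poisson (KL)
objective with automatic relevance determination: one relevance scale per
component, shared by the component's column of W and row of H, with an
exponential (L1) or half-normal (L2) prior; components whose relevance
collapses are pruned, so the effective number of signatures is inferred
rather than fixed.  Extracted signatures are matched to a reference catalog
by cosine similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_FLANKS = "ACGT"

#: Fixed category order: substitution blocks in SUBSTITUTIONS order, contexts
#: lexicographic by (5' base, 3' base) within each block.  Labels "A[C>A]A".
CATEGORIES_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _FLANKS
    for three in _FLANKS
)
CATEGORY_INDEX = {c: i for i, c in enumerate(CATEGORIES_96)}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def snv_category(ref: str, alt: str, context: str) -> str:
    """96-category label for an SNV, folding purine refs onto the pyrimidine strand."""
    if context[1] != ref:
        raise ValueError(f"context middle base {context[1]} != ref {ref}")
    if ref in "AG":
        context = reverse_complement(context)
        ref = context[1]
        alt = alt.translate(_COMPLEMENT)
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    if label not in CATEGORY_INDEX:
        raise ValueError(f"invalid category {label}")
    return label


@dataclass
class ContextMatrix:
    """96 x N nonnegative count matrix in the fixed category order."""

    counts: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96, len(self.sample_ids)):
            raise ValueError("counts must be 96 x n_samples")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(CATEGORIES_96), columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ContextMatrix":
        if list(df.index) != list(CATEGORIES_96):
            df = df.reindex(list(CATEGORIES_96))
            if df.isna().any().any():
                raise ValueError("frame does not cover the 96 categories")
        return cls(df.to_numpy(dtype=float), list(df.columns))


def classify_96(mutations, sample_ids: Sequence[str]) -> ContextMatrix:
    """Tally SNVs with contexts into the 96-category matrix.

    SNVs without a context (and all indels) are skipped with a logged count;
    each context-bearing SNV increments exactly one cell.
    """
    samp_ix = {s: j for j, s in enumerate(sample_ids)}
    counts = np.zeros((96, len(sample_ids)), dtype=float)
    n_skipped = 0
    for m in mutations:
        if not m.is_snv or m.context is None:
            n_skipped += 1
            continue
        counts[CATEGORY_INDEX[snv_category(m.ref, m.alt, m.context)],
               samp_ix[m.sample_id]] += 1
    if n_skipped:
        logger.info("classify_96: skipped %d records without usable context", n_skipped)
    return ContextMatrix(counts, list(sample_ids))


# ---------------------------------------------------------------------------
# Reference catalog


@dataclass
class ReferenceCatalog:
    """Named reference signature profiles over the fixed 96-category order."""

    names: list[str]
    profiles: np.ndarray  # 96 x R, columns sum to 1

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (96, len(self.names)):
            raise ValueError("profiles must be 96 x n_names")
        sums = self.profiles.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("catalog columns must sum to 1")

    def profile(self, name: str) -> np.ndarray:
        return self.profiles[:, self.names.index(name)]

    @classmethod
    def from_tsv(cls, path) -> "ReferenceCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        if list(df.index) != list(CATEGORIES_96):
            df = df.reindex(list(CATEGORIES_96))
            if df.isna().any().any():
                raise ValueError(f"catalog {path} does not cover the 96 categories")
        return cls(list(df.columns), df.to_numpy(dtype=float))


def load_default_catalog() -> ReferenceCatalog:
    """Packaged reference catalog (COSMIC v2 dialect; see file header)."""
    ref = resources.files("tmbsubtype.data") / "cosmic_v2_style_catalog.tsv"
    with resources.as_file(ref) as path:
        return ReferenceCatalog.from_tsv(path)


# ---------------------------------------------------------------------------
# ARD-NMF


@dataclass
class SignatureModel:
    """Result of an ARD-NMF fit.

    ``w`` has unit-sum columns (the signatures); ``h`` carries the activity
    scale so that ``w @ h`` reconstructs the count matrix.  Components are
    ordered by decreasing total attributed mutations and named W1, W2, ...
    """

    w: np.ndarray  # 96 x K_effective, columns sum to 1
    h: np.ndarray  # K_effective x N
    relevance: np.ndarray  # per-component ARD scale, same order
    k_effective: int
    reconstruction_error: float  # KL divergence of the final fit
    objective: float  # final penalized (MAP) objective, for restart selection
    sample_ids: list[str]
    objective_trace: tuple[float, ...] | None = None  # per-sweep MAP objective

    @property
    def names(self) -> list[str]:
        return [f"W{i + 1}" for i in range(self.k_effective)]


def _kl_divergence(v: np.ndarray, wh: np.ndarray) -> float:
    wh = np.maximum(wh, 1e-300)
    mask = v > 0
    return float(
        np.sum(v[mask] * np.log(v[mask] / wh[mask])) - v.sum() + wh.sum()
    )


def _ard_objective(
    v, w, h, lam, a: float, b: float, prior: str
) -> float:
    """MAP objective: KL divergence plus ARD prior terms (lower is better)."""
    f, n = v.shape[0], v.shape[1]
    kl = _kl_divergence(v, w @ h)
    if prior == "L1":
        penalty = np.sum((w.sum(axis=0) + h.sum(axis=1) + b) / lam) + (
            f + n + a + 1
        ) * np.sum(np.log(lam))
    else:  # L2 half-normal
        penalty = np.sum(
            ((w**2).sum(axis=0) + (h**2).sum(axis=1)) / (2 * lam) + b / lam
        ) + ((f + n) / 2 + a + 1) * np.sum(np.log(lam))
    return kl + float(penalty)


def bayesian_nmf(
    context_matrix: ContextMatrix | np.ndarray,
    k_max: int = 20,
    prior: str = "L1",
    max_iter: int = 3000,
    tol: float = 1e-8,
    seed: int | None = None,
    n_restarts: int = 10,
    a: float = 25.0,
    b: float = 1.0,
    prune_rel: float = 1e-3,
    track_objective: bool = False,
) -> SignatureModel:
    """Fit NMF with automatic relevance determination to a count matrix.

    Multiplicative updates under the Poisson/KL objective; one relevance
    hyperparameter per component, shared by that component's column of W and
    row of H, updated in closed form each sweep.  Components whose relevance
    falls below ``prune_rel`` times the largest are removed; the best of
    ``n_restarts`` runs by final MAP objective is returned.  Deterministic
    given ``seed``.
    """
    if isinstance(context_matrix, ContextMatrix):
        v = context_matrix.counts
        sample_ids = context_matrix.sample_ids
    else:
        v = np.asarray(context_matrix, dtype=float)
        sample_ids = [f"S{j}" for j in range(v.shape[1])]
    if v.ndim != 2 or v.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if (v < 0).any():
        raise ValueError("counts must be nonnegative")
    if not v.any():
        raise ValueError("all-zero count matrix")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if prior not in ("L1", "L2"):
        raise ValueError("prior must be 'L1' or 'L2'")

    rng = np.random.default_rng(seed)
    best: tuple[float, tuple] | None = None
    best_trace: list[float] | None = None
    for _ in range(max(1, n_restarts)):
        run_seed = rng.integers(0, 2**63 - 1)
        trace: list[float] | None = [] if track_objective else None
        result = _fit_once(
            v, k_max, prior, max_iter, tol, run_seed, a, b, prune_rel, trace
        )
        if best is None or result[0] < best[0]:
            best = result
            best_trace = trace
    objective, (w, h, lam) = best

    # order components by total attributed mutations, descending
    totals = h.sum(axis=1) * w.sum(axis=0)
    order = np.argsort(-totals, kind="stable")
    w, h, lam = w[:, order], h[order], lam[order]
    scale = w.sum(axis=0)
    w = w / scale
    h = h * scale[:, None]
    return SignatureModel(
        w=w,
        h=h,
        relevance=lam,
        k_effective=w.shape[1],
        reconstruction_error=_kl_divergence(v, w @ h),
        objective=objective,
        sample_ids=list(sample_ids),
        objective_trace=tuple(best_trace) if best_trace is not None else None,
    )


def _fit_once(v, k_max, prior, max_iter, tol, seed, a, b, prune_rel, trace=None):
    f, n = v.shape
    rng = np.random.default_rng(seed)
    mean_v = v.mean()
    # data-scaled init so WH starts near the magnitude of V
    scale = np.sqrt(mean_v / k_max)
    w = scale * rng.uniform(0.5, 1.5, size=(f, k_max))
    h = scale * rng.uniform(0.5, 1.5, size=(k_max, n))
    eps = np.finfo(float).tiny

    lam = np.full(k_max, np.inf)
    prev_obj = np.inf
    for it in range(max_iter):
        wh = w @ h + eps
        ratio = v / wh
        if prior == "L1":
            lam = (w.sum(axis=0) + h.sum(axis=1) + b) / (f + n + a + 1)
            w *= (ratio @ h.T) / (h.sum(axis=1)[None, :] + 1.0 / lam[None, :] + eps)
            wh = w @ h + eps
            ratio = v / wh
            h *= (w.T @ ratio) / (w.sum(axis=0)[:, None] + 1.0 / lam[:, None] + eps)
        else:
            lam = ((w**2).sum(axis=0) + (h**2).sum(axis=1) + 2 * b) / (
                f + n + 2 * a + 2
            )
            w *= (ratio @ h.T) / (h.sum(axis=1)[None, :] + w / lam[None, :] + eps)
            wh = w @ h + eps
            ratio = v / wh
            h *= (w.T @ ratio) / (w.sum(axis=0)[:, None] + h / lam[:, None] + eps)

        if trace is not None:
            trace.append(_ard_objective(v, w, h, lam, a, b, prior))
        if (it + 1) % 10 == 0 or it == max_iter - 1:
            obj = _ard_objective(v, w, h, lam, a, b, prior)
            if np.isfinite(prev_obj) and abs(prev_obj - obj) <= tol * abs(prev_obj):
                prev_obj = obj
                break
            prev_obj = obj

    # prune collapsed components by contribution to the reconstruction
    contrib = w.sum(axis=0) * h.sum(axis=1)
    keep = contrib > prune_rel * contrib.max()
    w, h, lam = w[:, keep], h[keep], lam[keep]
    obj = _ard_objective(v, w, h, lam, a, b, prior)
    return obj, (w, h, lam)


# ---------------------------------------------------------------------------
# Matching and per-sample attribution


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for zero-norm vector")
    return float(np.dot(u, v) / (nu * nv))


def cosine_match(
    model: SignatureModel, catalog: ReferenceCatalog
) -> list[tuple[str, str, float]]:
    """Best catalog match per extracted signature, independently.

    Returns ``(signature_name, reference_name, cosine)`` triples.
    """
    out = []
    for i, name in enumerate(model.names):
        sims = [
            cosine_similarity(model.w[:, i], catalog.profiles[:, r])
            for r in range(len(catalog.names))
        ]
        best = int(np.argmax(sims))
        out.append((name, catalog.names[best], float(sims[best])))
    return out


def signature_pattern(
    model: SignatureModel, context_matrix: ContextMatrix | None = None
) -> pd.DataFrame:
    """Per-sample attributed mutation counts per signature.

    Rows are signatures (W1..), columns samples.  When the fitted count
    matrix is supplied, H columns are rescaled so each sample's attributions
    sum exactly to its observed annotatable-SNV total; otherwise the
    reconstructed totals (equal up to fit error, since W columns sum to 1)
    are used as-is.
    """
    attr = model.h
    if context_matrix is not None:
        observed = context_matrix.counts.sum(axis=0)
        recon = model.h.sum(axis=0)
        scale = np.where(recon > 0, observed / np.maximum(recon, 1e-300), 0.0)
        attr = model.h * scale[None, :]
    return pd.DataFrame(attr, index=model.names, columns=model.sample_ids)


def compare_pattern_by_subtype(
    pattern: pd.DataFrame, subtypes, signature: str
) -> "TestResult":
    """Two-sided Wilcoxon rank-sum of one signature's attribution, TMB-H vs TMB-L."""
    from .stats_survival import TestResult, wilcoxon_rank_sum
    from .subtyping import Subtype

    label_by_sample = dict(zip(subtypes.sample_ids, subtypes.labels))
    values = pattern.loc[signature]
    high = [values[s] for s in pattern.columns if label_by_sample[s] is Subtype.TMB_H]
    low = [values[s] for s in pattern.columns if label_by_sample[s] is Subtype.TMB_L]
    if not high or not low:
        raise ValueError("both subtype groups must be non-empty")
    stat, p = wilcoxon_rank_sum(high, low, alternative="two-sided")
    return TestResult(
        test_name=f"wilcoxon[{signature}]~subtype",
        statistic=stat,
        p=p,
        group_sizes=(len(high), len(low)),
    )
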