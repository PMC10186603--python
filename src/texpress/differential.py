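"""Median-of-ratios normalization and a simplified NB Wald test.

Genes and TEs are analyzed jointly: one shared set of size factors, one
result table, one Benjamini–Hochberg correction across every tested
feature.  The Wald test is a deliberate simplification of the full
GLM machinery of standard DE tools: per-feature method-of-moments
dispersion (no shrinkage), group means of normalized counts, a
delta-method standard error for the log2 fold-change, and a two-sided
normal tail.  Downstream class-level statistics consume only the broad
behavior of the log2FC vector, which this estimator recovers.

log2FC convention: numerator group over denominator group, stabilized by
a pseudo-count of 0.5 on both group means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import CountMatrix, DE_COLUMNS, TableFormatError

LN2 = np.log(2.0)
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_ALPHA_FLOOR = 1e-8


class DifferentialError(ValueError):
    """Invalid input to the normalization/testing stage."""


@dataclass
class Contrast:
    """A binary group comparison (numerator over denominator)."""

    numerator: str
    denominator: str
    assignment: dict  # sample_id -> group label

    def __post_init__(self):
        num = self.numerator_samples()
        den = self.denominator_samples()
        if self.numerator == self.denominator:
            raise DifferentialError("contrast groups must be distinct")
        for label, ids in ((self.numerator, num), (self.denominator, den)):
            if len(ids) < 2:
                raise DifferentialError(
                    f"group {label!r} has {len(ids)} samples; need >= 2"
                )

    @classmethod
    def from_metadata(cls, metadata: pd.DataFrame, numerator: str,
                      denominator: str, column: str = "group") -> "Contrast":
        if column not in metadata.columns:
            raise DifferentialError(f"metadata has no column {column!r}")
        labels = set(metadata[column])
        for g in (numerator, denominator):
            if g not in labels:
                raise DifferentialError(
                    f"group {g!r} absent from metadata column {column!r}"
                )
        assignment = {
            str(s): str(g)
            for s, g in zip(metadata["sample_id"], metadata[column])
            if g in (numerator, denominator)
        }
        return cls(numerator, denominator, assignment)

    def numerator_samples(self):
        return [s for s, g in self.assignment.items() if g == self.numerator]

    def denominator_samples(self):
        return [s for s, g in self.assignment.items() if g == self.denominator]

    def group_indices(self, sample_ids):
        idx = {s: i for i, s in enumerate(sample_ids)}
        missing = [s for s in self.assignment if s not in idx]
        if missing:
            raise DifferentialError(
                f"contrast samples absent from count matrix: {missing[:5]}"
            )
        num = np.array([idx[s] for s in self.numerator_samples()], dtype=int)
        den = np.array([idx[s] for s in self.denominator_samples()], dtype=int)
        return num, den


def size_factors(counts: CountMatrix, pseudo_reference: bool = False) -> np.ndarray:
    """Median-of-ratios size factors (one positive real per sample).

    Reference features are those with positive counts in every sample; each
    sample's factor is the median over reference features of
    count / geometric mean.  With ``pseudo_reference=True`` the geometric
    mean of each feature is taken over its positive entries only and zeros
    are ignored in the median, accommodating sparse matrices with no
    all-positive feature.
    """
    v = counts.values
    if v.shape[0] == 0 or v.shape[1] == 0:
        raise DifferentialError("cannot compute size factors of an empty matrix")
    with np.errstate(divide="ignore"):
        logs = np.log(v)
    if pseudo_reference:
        pos = v > 0
        usable = pos.any(axis=1)
        if not usable.any():
            raise DifferentialError("all-zero count matrix")
        loggeo = np.where(
            usable,
            np.where(pos, logs, 0.0).sum(axis=1) / np.maximum(pos.sum(axis=1), 1),
            np.nan,
        )
        factors = np.empty(v.shape[1])
        for j in range(v.shape[1]):
            ratios = logs[:, j][usable & pos[:, j]] - loggeo[usable & pos[:, j]]
            if ratios.size == 0:
                raise DifferentialError(
                    f"sample {counts.sample_ids[j]!r} shares no positive feature "
                    "with the pseudo-reference"
                )
            factors[j] = np.exp(np.median(ratios))
        return factors
    reference = (v > 0).all(axis=1)
    if not reference.any():
        raise DifferentialError(
            "no feature is positive in all samples; rerun with "
            "pseudo_reference=True to use a positive-entry fallback"
        )
    loggeo = logs[reference].mean(axis=1)
    return np.exp(np.median(logs[reference] - loggeo[:, None], axis=0))


def normalize_counts(counts: CountMatrix, factors: np.ndarray) -> CountMatrix:
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (counts.n_samples,) or (factors <= 0).any():
        raise DifferentialError("need one positive size factor per sample")
    return CountMatrix(
        counts.values / factors[None, :],
        counts.feature_ids,
        counts.sample_ids,
        normalized=True,
    )


def estimate_dispersions(counts: CountMatrix, factors: np.ndarray,
                         contrast: Contrast,
                         alpha_floor: float = DEFAULT_ALPHA_FLOOR) -> pd.DataFrame:
    """Method-of-moments NB dispersion per feature, pooled within groups.

    On normalized counts restricted to the contrast's samples:
    ``alpha = max(alpha_floor, (pooled within-group variance - grand mean)
    / grand mean**2)``.  No shrinkage; degenerate features get the floor.
    """
    norm = normalize_counts(counts, factors)
    num, den = contrast.group_indices(norm.sample_ids)
    x1, x0 = norm.values[:, num], norm.values[:, den]
    n1, n0 = len(num), len(den)
    grand = np.concatenate([x1, x0], axis=1).mean(axis=1)
    pooled_var = (
        (n1 - 1) * x1.var(axis=1, ddof=1) + (n0 - 1) * x0.var(axis=1, ddof=1)
    ) / (n1 + n0 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - grand) / grand**2
    alpha = np.where(np.isfinite(alpha), alpha, alpha_floor)
    method = np.where(alpha > alpha_floor, "moments", "floor")
    alpha = np.maximum(alpha, alpha_floor)
    return pd.DataFrame(
        {"feature_id": list(counts.feature_ids), "alpha": alpha, "method": method}
    )


def wald_test(counts: CountMatrix, factors: np.ndarray,
              dispersions: pd.DataFrame, contrast: Contrast,
              pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Per-feature log2FC with delta-method Wald p and joint BH correction.

    ``base_mean`` is the mean normalized count over all samples in the
    matrix.  The variance of each group mean combines the NB variance of
    every sample's count (``mu + alpha mu**2`` with ``mu`` the fitted group
    mean scaled by that sample's size factor) propagated through the
    normalization; the log transform contributes the usual
    ``1 / ((m + pc) ln 2)**2`` factor.  A feature that is all zero in both
    groups has log2FC exactly 0 and p = 1.
    """
    factors = np.asarray(factors, dtype=float)
    norm = normalize_counts(counts, factors)
    alpha = (
        dispersions.set_index("feature_id")
        .loc[list(counts.feature_ids), "alpha"]
        .to_numpy(dtype=float)
    )
    num, den = contrast.group_indices(norm.sample_ids)
    base_mean = norm.values.mean(axis=1)
    m1 = norm.values[:, num].mean(axis=1)
    m0 = norm.values[:, den].mean(axis=1)
    pc = float(pseudocount)
    log2fc = np.log2(m1 + pc) - np.log2(m0 + pc)

    # Var of a group mean of normalized counts under NB sampling:
    # sum_j (m_g / sf_j + alpha m_g^2) / n_g^2 for samples j in the group.
    inv_sf_num = (1.0 / factors[num]).sum()
    inv_sf_den = (1.0 / factors[den]).sum()
    var_m1 = (m1 * inv_sf_num + alpha * m1**2 * len(num)) / len(num) ** 2
    var_m0 = (m0 * inv_sf_den + alpha * m0**2 * len(den)) / len(den) ** 2
    se = np.sqrt(
        var_m1 / ((m1 + pc) * LN2) ** 2 + var_m0 / ((m0 + pc) * LN2) ** 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    wald_p = np.where(
        se > 0,
        2.0 * stats.norm.sf(np.abs(z)),
        np.where(log2fc == 0.0, 1.0, 0.0),
    )
    adj_p = multipletests(wald_p, method="fdr_bh")[1] if len(wald_p) else wald_p
    return pd.DataFrame(
        {
            "feature_id": list(counts.feature_ids),
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "wald_p": wald_p,
            "adj_p": adj_p,
        },
        columns=list(DE_COLUMNS),
    )


def filter_low_counts(results: pd.DataFrame, min_mean: float = 10.0) -> pd.DataFrame:
    """Keep features whose base_mean strictly exceeds ``min_mean``.

    The strict ``> min_mean`` screen guards the class-level statistics
    against low-count normalization artifacts.
    """
    if "base_mean" not in results.columns:
        raise TableFormatError("results lack a base_mean column")
    return results.loc[results["base_mean"] > float(min_mean)].reset_index(drop=True)


def run_differential(counts: CountMatrix, metadata: pd.DataFrame, numerator: str,
                     denominator: str, column: str = "group",
                     pseudo_reference: bool = False,
                     pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Convenience wrapper: size factors -> dispersions -> Wald table."""
    contrast = Contrast.from_metadata(metadata, numerator, denominator, column)
    factors = size_factors(counts, pseudo_reference=pseudo_reference)
    disp = estimate_dispersions(counts, factors, contrast)
    return wald_test(counts, factors, disp, contrast, pseudocount=pseudocount)
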