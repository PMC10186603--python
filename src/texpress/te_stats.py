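"""Class-level and sample-level statistics for TE dysregulation.

The centerpiece is a rank test of each TE class's log2 fold-changes
against the global transcriptome fold-change location: library-wide
artifacts shift genes and TEs alike, so a class whose log2FCs sit above
the mean log2FC of *all* sufficiently expressed transcripts carries a
TE-specific signal.  A broad class shift can be highly significant even
when no individual TE survives FDR correction.

Also here: Pearson and covariate-corrected (partial) correlations of TE
abundance with age, per-sample total TE counts, deterministic age/sex
matching of subject groups, the ">mean log2FC" rule for the most
increased TEs, and exact set-intersection bookkeeping across contrasts.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    TE_CLASSES,
    TE_KIND,
    CorrelationResult,
    CountMatrix,
    TypeTestResult,
)

# Shapiro-Wilk is evaluated on at most this many values (fixed-seed
# subsample above it), a standard implementation limit of the statistic.
SHAPIRO_MAX_N = 5000
DEFAULT_MIN_CLASS_SIZE = 3
DEFAULT_EXACT_THRESHOLD = 25


class TEStatsError(ValueError):
    """Invalid input to a TE-level statistic."""


# --- global reference and class-level test --------------------------------


def global_reference_log2fc(results: pd.DataFrame) -> float:
    """Mean log2FC over all (count-filtered) transcripts, genes and TEs alike."""
    if len(results) == 0:
        raise TEStatsError("cannot take the global mean of an empty result set")
    return float(np.mean(results["log2fc"].to_numpy(dtype=float)))


def mann_whitney_location(class_values, reference_values,
                          exact_threshold: int = DEFAULT_EXACT_THRESHOLD):
    """Two-sided Mann-Whitney U of class vs reference log2FCs.

    Exact enumeration when the smaller sample has at most
    ``exact_threshold`` values (the exact distribution assumes continuity
    and applies no tie correction); tie-corrected normal approximation
    otherwise.  Returns ``(U, p, method)``.
    """
    x = np.asarray(class_values, dtype=float)
    y = np.asarray(reference_values, dtype=float)
    method = "exact" if min(len(x), len(y)) <= exact_threshold else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), method


def wilcoxon_vs_reference(class_values, reference_mean: float):
    """One-sample signed-rank of (class log2FC - reference mean) against 0.

    All differences exactly zero is a defined degenerate result (W=0, p=1),
    not an error.
    """
    d = np.asarray(class_values, dtype=float) - float(reference_mean)
    if np.all(d == 0):
        return 0.0, 1.0
    res = stats.wilcoxon(d, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def _shapiro(values, seed: int = 0):
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        return float("nan"), float("nan")
    if len(v) > SHAPIRO_MAX_N:
        rng = np.random.default_rng(seed)
        v = rng.choice(v, size=SHAPIRO_MAX_N, replace=False)
    if np.ptp(v) == 0:
        return float("nan"), float("nan")
    res = stats.shapiro(v)
    return float(res.statistic), float(res.pvalue)


def te_type_test(results: pd.DataFrame, annotation, te_class: str,
                 mode: str = "two_sample",
                 min_class_size: int = DEFAULT_MIN_CLASS_SIZE,
                 exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
                 reference: str = "all", shapiro_seed: int = 0):
    """Test one TE class's log2FCs against the global fold-change location.

    ``results`` must already be count-filtered.  ``reference="all"``
    compares the class with the full filtered log2FC vector (the default:
    "all transcripts" includes the TEs themselves); ``"genes_only"``
    restricts the reference to gene features.  The Shapiro-Wilk screen is
    reported but never gates the rank test.  A class smaller than
    ``min_class_size`` is returned flagged untestable with no p-value.
    """
    if mode not in ("two_sample", "one_sample"):
        raise TEStatsError(f"unknown test mode {mode!r}")
    if reference not in ("all", "genes_only"):
        raise TEStatsError(f"unknown reference {reference!r}")
    by_id = {r.feature_id: r for r in annotation}
    kinds = results["feature_id"].map(
        lambda f: by_id[f].kind if f in by_id else ""
    )
    classes = results["feature_id"].map(
        lambda f: by_id[f].te_class if f in by_id else ""
    )
    lfc = results["log2fc"].to_numpy(dtype=float)
    class_mask = (kinds == TE_KIND).to_numpy() & (classes == te_class).to_numpy()
    class_lfc = lfc[class_mask]
    ref_lfc = lfc[(kinds == "gene").to_numpy()] if reference == "genes_only" else lfc
    if len(ref_lfc) == 0:
        raise TEStatsError("empty reference set")
    ref_mean = float(np.mean(ref_lfc))

    n_te = int(class_mask.sum())
    median_lfc = float(np.median(class_lfc)) if n_te else float("nan")
    w, w_p = _shapiro(class_lfc, seed=shapiro_seed)
    if n_te < min_class_size:
        return TypeTestResult(
            te_class=te_class, n_te=n_te, median_log2fc=median_lfc,
            reference_mean=ref_mean, shapiro_W=w, shapiro_p=w_p,
            test_mode=mode, U_or_W=float("nan"), p_value=float("nan"),
            untestable=True,
        )
    if mode == "two_sample":
        stat, p, _ = mann_whitney_location(class_lfc, ref_lfc, exact_threshold)
    else:
        stat, p = wilcoxon_vs_reference(class_lfc, ref_mean)
    return TypeTestResult(
        te_class=te_class, n_te=n_te, median_log2fc=median_lfc,
        reference_mean=ref_mean, shapiro_W=w, shapiro_p=w_p,
        test_mode=mode, U_or_W=stat, p_value=p,
    )


def te_type_tests(results: pd.DataFrame, annotation, classes=TE_CLASSES,
                  include_other: bool = False, **kwargs):
    """Run :func:`te_type_test` for each class; ``other`` excluded by default."""
    classes = list(classes)
    if include_other and "other" not in classes:
        classes.append("other")
    return [te_type_test(results, annotation, c, **kwargs) for c in classes]


# --- correlations ---------------------------------------------------------


def _pearson_with_df(x, y, df: int):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise TEStatsError("zero variance in correlation input")
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    if df <= 0:
        return r, float("nan")
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return r, float(2.0 * stats.t.sf(abs(t), df))


def pearson_correlation(x, y, scope: str = "per_TE", name: str = "") -> CorrelationResult:
    """Pearson r with a two-sided t-based p on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise TEStatsError("need matched vectors with n >= 3")
    r, p = _pearson_with_df(x, y, len(x) - 2)
    return CorrelationResult(scope=scope, name=name, r=r, p=p, partial=False,
                             covariates=(), n=len(x))


def partial_correlation(x, y, covariates=None, scope: str = "per_TE",
                        name: str = "") -> CorrelationResult:
    """Pearson correlation of x and y after residualizing both on covariates.

    Covariates enter with an intercept by least squares; the p-value uses
    n - 2 - k degrees of freedom.  With no covariates this reduces exactly
    to :func:`pearson_correlation`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        cov = np.empty((len(x), 0))
        names = []
    elif isinstance(covariates, pd.DataFrame):
        names = [str(c) for c in covariates.columns]
        cov = covariates.to_numpy(dtype=float)
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        names = [f"c{i + 1}" for i in range(cov.shape[1])]
    k = cov.shape[1]
    if len(x) != len(y) or cov.shape[0] != len(x):
        raise TEStatsError("x, y and covariates must have matching length")
    if len(x) < 3 + k:
        raise TEStatsError(f"need n >= {3 + k} samples for {k} covariates")
    design = np.column_stack([np.ones(len(x)), cov])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        collinear = _collinear_columns(design, names)
        raise TEStatsError(f"rank-deficient covariates: {collinear}")
    if k:
        rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
        ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    else:
        rx, ry = x, y
    r, p = _pearson_with_df(rx, ry, len(x) - 2 - k)
    return CorrelationResult(scope=scope, name=name, r=r, p=p, partial=k > 0,
                             covariates=tuple(names), n=len(x))


def _collinear_columns(design, names):
    """Name covariate columns that do not add rank over the intercept."""
    bad = []
    base = design[:, :1]
    for j, name in enumerate(names):
        cand = np.column_stack([base, design[:, j + 1]])
        if np.linalg.matrix_rank(cand) == np.linalg.matrix_rank(base):
            bad.append(name)
            continue
        base = cand
    return bad or names


def encode_covariates(metadata: pd.DataFrame, covariates) -> pd.DataFrame:
    """Expand metadata covariates for residualization.

    Categorical columns (e.g. sex) become 0/1 indicators dropping the
    first level; numeric columns pass through.  Rows with missing values
    must be removed by the caller beforehand.
    """
    cols = {}
    for name in covariates:
        if name not in metadata.columns:
            raise TEStatsError(f"metadata has no covariate column {name!r}")
        col = metadata[name]
        if col.dtype == object:
            levels = sorted(set(col))
            for lev in levels[1:]:
                cols[f"{name}_{lev}"] = (col == lev).astype(float).to_numpy()
        else:
            cols[name] = col.to_numpy(dtype=float)
    return pd.DataFrame(cols, index=metadata.index)


def total_te_counts(norm_counts: CountMatrix, annotation, by_class: bool = False):
    """Per-sample sums of normalized TE counts, in total or per class.

    Returns a Series (total) or a class x sample DataFrame.
    """
    if not norm_counts.normalized:
        raise TEStatsError("total TE counts are computed on normalized counts")
    te_class = {
        r.feature_id: r.te_class for r in annotation if r.kind == TE_KIND
    }
    rows = np.array(
        [te_class.get(f, "") for f in norm_counts.feature_ids], dtype=object
    )
    samples = list(norm_counts.sample_ids)
    if not by_class:
        mask = rows != ""
        totals = norm_counts.values[mask].sum(axis=0) if mask.any() \
            else np.zeros(len(samples))
        return pd.Series(totals, index=samples, name="total_TE")
    out = {}
    for cls in TE_CLASSES + ("other",):
        mask = rows == cls
        out[cls] = norm_counts.values[mask].sum(axis=0) if mask.any() \
            else np.zeros(len(samples))
    return pd.DataFrame(out, index=samples).T


# --- matching -------------------------------------------------------------


def match_groups(metadata: pd.DataFrame, group_label: str = "group",
                 n_per_group: int = 10, objective: str = "pair",
                 age_col: str = "age", sex_col: str = "sex",
                 extreme_labels=("young", "old")):
    """Select sex-balanced, age-matched samples for a binary comparison.

    ``objective="pair"``: for the two labels in ``metadata[group_label]``,
    greedily pair cases and controls within each sex stratum by minimal
    absolute age difference (smallest differences first, sample-id
    lexicographic tie-break) and keep ``n_per_group`` pairs.

    ``objective="extremes"``: ignore existing labels and pick the
    ``n_per_group`` oldest and youngest subjects with identical sex
    composition in both groups, maximizing the age gap.

    Returns ``{label: [sample ids]}``.
    """
    for col in (age_col, sex_col):
        if col not in metadata.columns:
            raise TEStatsError(f"metadata has no column {col!r}")
    md = metadata.reset_index(drop=True)
    if objective == "pair":
        return _match_pairs(md, group_label, n_per_group, age_col, sex_col)
    if objective == "extremes":
        return _match_extremes(md, n_per_group, age_col, sex_col, extreme_labels)
    raise TEStatsError(f"unknown matching objective {objective!r}")


def _match_pairs(md, group_label, n_per_group, age_col, sex_col):
    if group_label not in md.columns:
        raise TEStatsError(f"metadata has no column {group_label!r}")
    labels = sorted(set(md[group_label]))
    if len(labels) != 2:
        raise TEStatsError(
            f"pair matching needs exactly 2 group labels, found {labels}"
        )
    a_label, b_label = labels
    for label in labels:
        n_avail = int((md[group_label] == label).sum())
        if n_avail < n_per_group:
            raise TEStatsError(
                f"group {label!r} has {n_avail} candidates; need {n_per_group}"
            )
    candidates = []
    for sex in sorted(set(md[sex_col])):
        stratum = md[md[sex_col] == sex]
        cases = stratum[stratum[group_label] == a_label]
        controls = stratum[stratum[group_label] == b_label]
        for _, c in cases.iterrows():
            for _, k in controls.iterrows():
                candidates.append(
                    (
                        abs(float(c[age_col]) - float(k[age_col])),
                        str(c["sample_id"]),
                        str(k["sample_id"]),
                    )
                )
    candidates.sort()
    used = set()
    pairs = []
    for _, ca, co in candidates:
        if ca in used or co in used:
            continue
        used.update((ca, co))
        pairs.append((ca, co))
        if len(pairs) == n_per_group:
            break
    if len(pairs) < n_per_group:
        raise TEStatsError(
            f"infeasible sex balance: only {len(pairs)} sex-matched pairs "
            f"achievable, {n_per_group} requested"
        )
    return {
        a_label: [p[0] for p in pairs],
        b_label: [p[1] for p in pairs],
    }


def _match_extremes(md, n_per_group, age_col, sex_col, extreme_labels):
    young_label, old_label = extreme_labels
    sexes = sorted(set(md[sex_col]))
    # Per-sex quotas as even as possible, extra slots to the larger stratum
    # (lexicographic sex label breaks exact ties).
    sizes = {s: int((md[sex_col] == s).sum()) for s in sexes}
    quotas = {s: n_per_group // len(sexes) for s in sexes}
    remainder = n_per_group - sum(quotas.values())
    for s in sorted(sexes, key=lambda s: (-sizes[s], s)):
        if remainder == 0:
            break
        quotas[s] += 1
        remainder -= 1
    young, old = [], []
    for s in sexes:
        stratum = md[md[sex_col] == s].copy()
        q = quotas[s]
        if len(stratum) < 2 * q:
            raise TEStatsError(
                f"infeasible sex balance: stratum {s!r} has {len(stratum)} "
                f"samples, needs {2 * q}; achievable split is "
                f"{len(stratum) // 2} per group"
            )
        ordered = stratum.sort_values(
            [age_col, "sample_id"], kind="mergesort"
        )["sample_id"].tolist()
        young.extend(ordered[:q])
        old.extend(ordered[-q:])
    return {young_label: sorted(young), old_label: sorted(old)}


# --- selection and intersection ------------------------------------------


def most_increased_tes(results: pd.DataFrame, annotation=None) -> set:
    """TEs with log2FC strictly greater than the mean log2FC over all TEs."""
    df = results
    if annotation is not None:
        te_ids = {r.feature_id for r in annotation if r.kind == TE_KIND}
        df = df[df["feature_id"].isin(te_ids)]
    if len(df) == 0:
        raise TEStatsError("no TE results to select from")
    lfc = df["log2fc"].to_numpy(dtype=float)
    mean = lfc.mean()
    return set(df.loc[lfc > mean, "feature_id"])


def intersect_te_sets(named_sets) -> "TESetOverlap":
    """Exact membership bookkeeping of 2-6 named TE sets.

    Every TE in the union is assigned its bit pattern over the ordered set
    names ('1' = member); ``region_counts`` covers all nonempty patterns
    exhaustively and disjointly.
    """
    names = list(named_sets)
    if not (2 <= len(names) <= 6):
        raise TEStatsError(
            f"need between 2 and 6 sets, got {len(names)}"
        )
    sets = {n: set(named_sets[n]) for n in names}
    union = sorted(set().union(*sets.values()))
    membership = pd.DataFrame(
        {n: [te in sets[n] for te in union] for n in names},
        index=union,
    )
    patterns = [
        "".join(bits)
        for bits in itertools.product("01", repeat=len(names))
        if "1" in bits
    ]
    region_counts = {p: 0 for p in patterns}
    for te in union:
        pattern = "".join("1" if te in sets[n] else "0" for n in names)
        region_counts[pattern] += 1
    return TESetOverlap(tuple(names), membership, region_counts)


class TESetOverlap:
    """Membership patterns and region counts for a family of TE sets."""

    def __init__(self, set_names, membership, region_counts):
        self.set_names = tuple(set_names)
        self.membership = membership
        self.region_counts = dict(region_counts)
        if sum(self.region_counts.values()) != len(self.membership):
            raise TEStatsError("region counts do not sum to the union size")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (pattern, count) for pattern, count in sorted(self.region_counts.items())
        ]
        df = pd.DataFrame(rows, columns=["pattern", "count"])
        for i, name in enumerate(self.set_names):
            df[name] = [p[i] == "1" for p in df["pattern"]]
        return df
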