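"""Synthetic bulk RNA-seq counts with a TE dysregulation signal and known truth.

The generator emulates the statistical structure the downstream analyses
assume: negative-binomial counts with per-sample size factors, gene log2
fold-changes centered at zero (the "evenly distributed" transcriptome
background), and a broad class-structured TE shift — many small positive
effects spread across most TEs of each class rather than a few large ones,
the regime in which no individual TE reaches significance but the class as
a whole does.  Ages are drawn uniformly on a configurable range (default
25–102 years, an adult human brain-bank span) with optional Gaussian-copula
confounding of age with sex and post-mortem interval, so covariate
correction has something real to remove.

The NB is parameterized by dispersion ``alpha`` with variance
``mu + alpha * mu**2``; ``alpha = 0`` degenerates to Poisson.  All
randomness flows from one integer seed through ``numpy``'s PCG64 streams,
so a fixed seed gives bit-identical output across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    TE_CLASSES,
    GENE_KIND,
    TE_KIND,
    AlignmentRecord,
    CountMatrix,
    FeatureAnnotation,
)


class SimConfigError(ValueError):
    """A simulation configuration field failed validation."""


def _default_te_counts():
    # Rough relative abundance of subfamilies per class in a repeatmasker
    # annotation: LINEs/SINEs dominate, DNA transposons are the minority.
    return {"LINE": 300, "SINE": 200, "LTR": 200, "DNA": 100}


def _default_te_shift():
    # Small positive shift shared by all major classes: the broad,
    # individually-insignificant increase the class-level test targets.
    return {c: 0.2 for c in TE_CLASSES}


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    log2 fold-changes refer to the ``group_labels[1]`` (e.g. old) over
    ``group_labels[0]`` (e.g. young) contrast.  ``age_slope_per_te`` is in
    log2 units per year of age, applied to TE features only and centered
    on the midpoint of ``age_range`` so it does not shift baselines.
    """

    n_genes: int = 2000
    n_tes_per_class: dict = field(default_factory=_default_te_counts)
    n_samples_per_group: int = 10
    baseline_log_mean: tuple = (math.log(100.0), 1.0)  # lognormal (loc, scale)
    dispersion: float = 0.1  # NB alpha: var = mu + alpha mu^2
    size_factor_range: tuple = (0.7, 1.4)
    gene_effect_sd: float = 0.15
    te_class_shift: dict = field(default_factory=_default_te_shift)
    te_effect_sd: float = 0.1
    age_slope_per_te: float = 0.0
    covariate_confounding: float = 0.0  # copula corr of age with sex & PMI
    age_range: tuple = (25.0, 102.0)
    pmi_log_params: tuple = (2.3, 0.5)  # lognormal hours, median ~10 h
    group_labels: tuple = ("young", "old")
    seed: int = 0

    def validate(self) -> "SimConfig":
        if int(self.n_genes) < 1:
            raise SimConfigError("n_genes must be >= 1")
        for cls, n in self.n_tes_per_class.items():
            if int(n) < 1:
                raise SimConfigError(f"n_tes_per_class[{cls!r}] must be >= 1")
        if int(self.n_samples_per_group) < 1:
            raise SimConfigError("n_samples_per_group must be >= 1")
        if self.dispersion < 0:
            raise SimConfigError("dispersion must be >= 0")
        lo, hi = self.size_factor_range
        if not (0 < lo <= hi):
            raise SimConfigError("size_factor_range must be positive with lo <= hi")
        for name in ("gene_effect_sd", "te_effect_sd"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if not (-1.0 < self.covariate_confounding < 1.0):
            raise SimConfigError("covariate_confounding must lie in (-1, 1)")
        a_lo, a_hi = self.age_range
        if not (0 <= a_lo <= a_hi):
            raise SimConfigError("age_range must be nonnegative with lo <= hi")
        if len(self.group_labels) != 2 or self.group_labels[0] == self.group_labels[1]:
            raise SimConfigError("group_labels must be two distinct labels")
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise SimConfigError(f"unknown SimConfig fields: {sorted(unknown)}")
        cfg = cls(**d)
        for name in ("baseline_log_mean", "size_factor_range", "age_range",
                     "pmi_log_params", "group_labels"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        for name in ("baseline_log_mean", "size_factor_range", "age_range",
                     "pmi_log_params", "group_labels"):
            d[name] = list(d[name])
        return d


@dataclass
class SimTruth:
    """Ground truth behind one simulated dataset, for recovery tests."""

    log2fc: pd.Series  # per-feature true group log2FC
    size_factors: pd.Series  # per-sample
    class_shifts: dict  # class -> delta_c
    age_slopes: pd.Series  # per-feature log2/year
    dispersion: float  # NB alpha used by the generator
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.log2fc.index,
                "true_log2fc": self.log2fc.to_numpy(),
                "age_slope": self.age_slopes.to_numpy(),
            }
        )


def _make_features(config: SimConfig):
    records = []
    for i in range(int(config.n_genes)):
        records.append(FeatureAnnotation(f"gene{i + 1:05d}", GENE_KIND))
    for cls in sorted(config.n_tes_per_class):
        for i in range(int(config.n_tes_per_class[cls])):
            records.append(
                FeatureAnnotation(
                    feature_id=f"{cls}_{i + 1:04d}",
                    kind=TE_KIND,
                    te_name=f"{cls}_{i + 1:04d}",
                    te_family=f"{cls}fam{i % 10 + 1}",
                    te_class=cls,
                )
            )
    return records


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson NB with variance mu + alpha mu^2 (Poisson at alpha=0)."""
    if alpha == 0:
        return rng.poisson(mu).astype(float)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, alpha * mu)
    return rng.poisson(lam).astype(float)


def simulate_counts(config: SimConfig):
    """Draw one synthetic study.

    Returns ``(CountMatrix, metadata DataFrame, [FeatureAnnotation], SimTruth)``.
    Counts are NB with mean ``size_factor * baseline * 2**(lfc * group +
    age_slope * (age - age_mid))`` and dispersion ``config.dispersion``.
    """
    config.validate()
    rng = np.random.default_rng(int(config.seed))
    records = _make_features(config)
    feature_ids = [r.feature_id for r in records]
    is_te = np.array([r.kind == TE_KIND for r in records])
    te_class = np.array([r.te_class for r in records], dtype=object)

    n = int(config.n_samples_per_group)
    n_samples = 2 * n
    sample_ids = [f"S{j + 1:03d}" for j in range(n_samples)]
    lab0, lab1 = config.group_labels
    group = np.array([lab0] * n + [lab1] * n, dtype=object)

    # Covariates via a Gaussian copula so age can be confounded with sex/PMI.
    rho = float(config.covariate_confounding)
    z = rng.standard_normal((n_samples, 3))
    z_age = z[:, 0]
    z_sex = rho * z_age + math.sqrt(1 - rho**2) * z[:, 1]
    z_pmi = rho * z_age + math.sqrt(1 - rho**2) * z[:, 2]
    a_lo, a_hi = config.age_range
    age = a_lo + (a_hi - a_lo) * stats.norm.cdf(z_age)
    sex = np.where(z_sex > 0, "M", "F")
    mu_pmi, sd_pmi = config.pmi_log_params
    pmi = np.exp(mu_pmi + sd_pmi * z_pmi)

    size_factors = rng.uniform(*config.size_factor_range, size=n_samples)
    baseline = rng.lognormal(*config.baseline_log_mean, size=len(feature_ids))

    lfc = rng.normal(0.0, config.gene_effect_sd, size=len(feature_ids))
    for cls in sorted(config.n_tes_per_class):
        delta = float(config.te_class_shift.get(cls, 0.0))
        mask = is_te & (te_class == cls)
        lfc[mask] = rng.normal(delta, config.te_effect_sd, size=int(mask.sum()))
    age_slopes = np.where(is_te, float(config.age_slope_per_te), 0.0)

    design = (group == lab1).astype(float)  # 1 for numerator group
    age_mid = 0.5 * (a_lo + a_hi)
    log2_effect = np.outer(lfc, design) + np.outer(age_slopes, age - age_mid)
    mu = size_factors[None, :] * baseline[:, None] * np.exp2(log2_effect)
    values = _nb_draw(rng, mu, float(config.dispersion))

    counts = CountMatrix(values, tuple(feature_ids), tuple(sample_ids))
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": group,
            "age": age,
            "sex": sex,
            "pmi": pmi,
        }
    )
    truth = SimTruth(
        log2fc=pd.Series(lfc, index=feature_ids),
        size_factors=pd.Series(size_factors, index=sample_ids),
        class_shifts=dict(config.te_class_shift),
        age_slopes=pd.Series(age_slopes, index=feature_ids),
        dispersion=float(config.dispersion),
        seed=int(config.seed),
    )
    return counts, metadata, records, truth


def simulate_alignments(abundances: dict, ambiguity: dict, seed: int = 0):
    """Toy alignment records: unique reads per feature plus two-hit reads per pair.

    Emits exactly ``abundances[f]`` single-hit reads for each feature and
    ``ambiguity[(f, g)]`` reads hitting both members of the pair; the order
    is a seed-determined shuffle but the multiset of records is fixed.
    """
    features = set(abundances)
    for count in abundances.values():
        if count < 0:
            raise SimConfigError("abundances must be >= 0")
    records = []
    k = 0
    for f in sorted(abundances):
        for _ in range(int(abundances[f])):
            k += 1
            records.append(AlignmentRecord(f"r{k:06d}", frozenset([f])))
    for pair in sorted(ambiguity):
        f, g = pair
        for x in (f, g):
            if x not in features:
                raise SimConfigError(f"ambiguity pair references unknown feature {x!r}")
        if ambiguity[pair] < 0:
            raise SimConfigError("ambiguity counts must be >= 0")
        for _ in range(int(ambiguity[pair])):
            k += 1
            records.append(AlignmentRecord(f"r{k:06d}", frozenset([f, g])))
    rng = np.random.default_rng(int(seed))
    order = rng.permutation(len(records))
    return [records[i] for i in order]
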