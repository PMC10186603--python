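"""End-to-end orchestration: simulate/load -> normalize -> DE -> TE statistics.

One YAML config drives a run; all randomness flows from a single root seed
through named per-stage substreams, so a rerun with the same config and
seed reproduces every deterministic artifact bit-identically.  Each run
writes a ``manifest.json`` listing every emitted file with its SHA-256
content hash (no timestamps), which is also how determinism is audited.

Logging emits one structured line per stage with the shapes and counts a
reviewer needs to audit the screens: features kept by the count filter,
reads assigned, TEs selected as "most increased".
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import data_model as dm
from . import differential as de
from . import te_stats as ts
from .synthetic import SimConfig, simulate_counts

logger = logging.getLogger("texpress")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is prefixed with the stage name."""


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one of ``sim`` (an embedded :class:`SimConfig`) or ``inputs``
    (paths to counts/metadata/annotation TSVs) must be present.
    ``contrast`` drives :func:`run_contrast`; ``contrasts`` (two to six
    entries) drives :func:`run_overlap_study`.
    """

    output_dir: str
    seed: int = 0
    sim: SimConfig | None = None
    inputs: dict | None = None  # {"counts":…, "metadata":…, "annotation":…}
    contrast: dict | None = None  # {"column","numerator","denominator"}
    contrasts: list = field(default_factory=list)
    min_mean: float = 10.0
    test_mode: str = "two_sample"
    reference: str = "all"
    covariates: tuple = ("sex", "pmi")
    classes: tuple = dm.TE_CLASSES
    pseudo_reference: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.sim is None) == (self.inputs is None):
            raise PipelineError(
                "config: exactly one of 'sim' and 'inputs' must be present"
            )
        if self.inputs is not None:
            missing = {"counts", "metadata", "annotation"} - set(self.inputs)
            if missing:
                raise PipelineError(f"config: inputs missing paths {sorted(missing)}")
        self.covariates = tuple(self.covariates)
        self.classes = tuple(self.classes)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d and d["sim"] is not None:
            d["sim"] = SimConfig.from_dict(d["sim"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = {
            "output_dir": self.output_dir,
            "seed": self.seed,
            "sim": self.sim.to_dict() if self.sim is not None else None,
            "inputs": self.inputs,
            "contrast": self.contrast,
            "contrasts": list(self.contrasts),
            "min_mean": self.min_mean,
            "test_mode": self.test_mode,
            "reference": self.reference,
            "covariates": list(self.covariates),
            "classes": list(self.classes),
            "pseudo_reference": self.pseudo_reference,
            "log_level": self.log_level,
        }
        return d


def _stage_seed(root_seed: int, stage: str) -> int:
    """Stable per-stage substream seed derived from the root seed (< 2^31)."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Run:
    """Bookkeeping for one pipeline run: staged execution plus a manifest."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = config.output_dir
        os.makedirs(self.outdir, exist_ok=True)
        logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
        self.files = {}
        self.stages = []

    def path(self, name: str) -> str:
        return os.path.join(self.outdir, name)

    def register(self, name: str) -> None:
        self.files[name] = {"path": name, "sha256": _sha256(self.path(name))}

    def stage(self, name: str, **info) -> None:
        logger.info("stage=%s %s", name,
                    " ".join(f"{k}={v}" for k, v in sorted(info.items())))
        self.stages.append({"stage": name, **info})

    def write_manifest(self) -> dict:
        manifest = {
            "config": self.config.to_dict(),
            "seed": self.config.seed,
            "files": dict(sorted(self.files.items())),
            "stages": self.stages,
        }
        with open(self.path("manifest.json"), "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest


def _load_or_simulate(run: _Run):
    config = run.config
    if config.sim is not None:
        sim_cfg = replace(config.sim, seed=_stage_seed(config.seed, "simulate"))
        counts, metadata, annotation, truth = simulate_counts(sim_cfg)
        dm.write_count_matrix(counts, run.path("counts.tsv"))
        dm.write_sample_metadata(metadata, run.path("metadata.tsv"))
        dm.write_te_annotation(annotation, run.path("annotation.tsv"))
        dm._write_frame(truth.to_frame(), run.path("truth.tsv"))
        for name in ("counts.tsv", "metadata.tsv", "annotation.tsv", "truth.tsv"):
            run.register(name)
        run.stage("simulate", n_features=counts.n_features,
                  n_samples=counts.n_samples, seed=sim_cfg.seed)
    else:
        counts = dm.read_count_matrix(config.inputs["counts"])
        metadata = dm.read_sample_metadata(config.inputs["metadata"])
        annotation = dm.read_te_annotation(config.inputs["annotation"])
        run.stage("load", n_features=counts.n_features, n_samples=counts.n_samples)
    return counts, metadata, annotation


def _wrap(stage):
    def deco(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"{stage}: {exc}") from exc
        return inner
    return deco


def _differential_stage(run: _Run, counts, metadata, contrast_spec):
    config = run.config
    column = contrast_spec.get("column", "group")
    contrast = de.Contrast.from_metadata(
        metadata, contrast_spec["numerator"], contrast_spec["denominator"], column
    )
    factors = de.size_factors(counts, pseudo_reference=config.pseudo_reference)
    norm = de.normalize_counts(counts, factors)
    disp = de.estimate_dispersions(counts, factors, contrast)
    det = de.wald_test(counts, factors, disp, contrast)
    return contrast, factors, norm, det


def run_contrast(config: RunConfig) -> dict:
    """Run one binary contrast end to end and return the output manifest."""
    if config.contrast is None:
        raise PipelineError("config: run_contrast needs a 'contrast' entry")
    run = _Run(config)
    counts, metadata, annotation = _wrap("input")(_load_or_simulate)(run)

    contrast, factors, norm, det = _wrap("differential")(_differential_stage)(
        run, counts, metadata, config.contrast
    )
    pd.DataFrame(
        {"sample_id": list(counts.sample_ids), "size_factor": factors}
    ).pipe(dm._write_frame, run.path("size_factors.tsv"))
    dm.write_count_matrix(norm, run.path("norm_counts.tsv"))
    dm.write_de_results(det, run.path("de.tsv"))
    for name in ("size_factors.tsv", "norm_counts.tsv", "de.tsv"):
        run.register(name)
    run.stage("differential", n_tested=len(det),
              numerator=contrast.numerator, denominator=contrast.denominator)

    def _te_stage():
        filtered = de.filter_low_counts(det, config.min_mean)
        results = ts.te_type_tests(
            filtered, annotation, classes=config.classes,
            mode=config.test_mode, reference=config.reference,
        )
        dm.write_de_results(filtered, run.path("de_filtered.tsv"))
        dm.write_type_test_results(results, run.path("typetest.tsv"))
        run.register("de_filtered.tsv")
        run.register("typetest.tsv")
        run.stage("te_type_test", n_filtered=len(filtered),
                  min_mean=config.min_mean, mode=config.test_mode)
        return filtered

    filtered = _wrap("te_type_test")(_te_stage)()

    def _corr_stage():
        if "age" not in metadata.columns:
            return
        usable = metadata.dropna(subset=["age"]).copy()
        covs = [c for c in config.covariates if c in usable.columns]
        if covs:
            usable = usable.dropna(subset=[c for c in covs
                                           if usable[c].dtype != object])
        norm_sub = norm.subset_samples(list(usable["sample_id"]))
        age = usable["age"].to_numpy(dtype=float)
        cov_frame = ts.encode_covariates(usable, covs) if covs else None
        results = []
        totals = ts.total_te_counts(norm_sub, annotation)
        results.append(ts.pearson_correlation(
            age, totals.to_numpy(), scope="total_TE", name="total_TE"))
        if cov_frame is not None and len(cov_frame.columns):
            results.append(ts.partial_correlation(
                age, totals.to_numpy(), cov_frame,
                scope="total_TE", name="total_TE"))
        by_class = ts.total_te_counts(norm_sub, annotation, by_class=True)
        for cls in config.classes:
            vals = by_class.loc[cls].to_numpy()
            if np.ptp(vals) == 0:
                continue
            results.append(ts.pearson_correlation(
                age, vals, scope="per_class", name=cls))
            if cov_frame is not None and len(cov_frame.columns):
                results.append(ts.partial_correlation(
                    age, vals, cov_frame, scope="per_class", name=cls))
        dm.write_correlation_results(results, run.path("corr.tsv"))
        run.register("corr.tsv")
        run.stage("age_correlation", n_samples=len(usable),
                  covariates=",".join(covs) or "-")

    _wrap("age_correlation")(_corr_stage)()

    most = ts.most_increased_tes(filtered, annotation) if len(filtered) else set()
    with open(run.path("most_increased.txt"), "w", encoding="utf-8") as fh:
        for te in sorted(most):
            fh.write(te + "\n")
    run.register("most_increased.txt")
    run.stage("most_increased", n_selected=len(most))

    return run.write_manifest()


def _resolve_contrast_metadata(metadata: pd.DataFrame, spec: dict) -> tuple:
    """Resolve one overlap-study contrast, deriving a median split if asked.

    A spec with ``derive_from: <numeric column>`` adds a two-level label
    column (``high``/``low`` halves around the median, ties to ``low``),
    mirroring upper/lower-50% splits of pathology or cognition scores.
    """
    md = metadata.copy()
    if "derive_from" in spec:
        src = spec["derive_from"]
        if src not in md.columns:
            raise PipelineError(f"overlap: no metadata column {src!r} to split")
        vals = md[src].to_numpy(dtype=float)
        med = float(np.nanmedian(vals))
        column = spec.get("column", f"{src}_split")
        md[column] = np.where(vals > med, "high", "low")
        numerator = spec.get("numerator", "high")
        denominator = spec.get("denominator", "low")
    else:
        column = spec.get("column", "group")
        numerator = spec["numerator"]
        denominator = spec["denominator"]
    return md, column, numerator, denominator


def run_overlap_study(config: RunConfig) -> dict:
    """Run >= 2 contrasts, select the most increased TEs in each, intersect."""
    if len(config.contrasts) == 1:
        raise PipelineError(
            "overlap: a single contrast cannot be intersected; use run_contrast"
        )
    if not (2 <= len(config.contrasts) <= 6):
        raise PipelineError(
            f"overlap: need 2-6 contrasts, got {len(config.contrasts)}"
        )
    run = _Run(config)
    counts, metadata, annotation = _wrap("input")(_load_or_simulate)(run)

    named_sets = {}
    for i, spec in enumerate(config.contrasts):
        name = spec.get("name", f"contrast{i + 1}")

        def _one(spec=spec, name=name):
            md, column, numerator, denominator = _resolve_contrast_metadata(
                metadata, spec
            )
            _, _, _, det = _differential_stage(
                run, counts, md,
                {"column": column, "numerator": numerator,
                 "denominator": denominator},
            )
            filtered = de.filter_low_counts(det, config.min_mean)
            dm.write_de_results(det, run.path(f"de_{name}.tsv"))
            run.register(f"de_{name}.tsv")
            selected = ts.most_increased_tes(filtered, annotation)
            run.stage(f"contrast_{name}", n_filtered=len(filtered),
                      n_selected=len(selected))
            return selected

        named_sets[name] = _wrap(f"contrast_{name}")(_one)()

    overlap = ts.intersect_te_sets(named_sets)
    dm._write_frame(overlap.to_frame(), run.path("overlap.tsv"))
    run.register("overlap.tsv")
    run.stage("overlap", n_union=len(overlap.membership))
    manifest = run.write_manifest()
    manifest["overlap"] = overlap
    return manifest
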