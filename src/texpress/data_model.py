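"""Core containers and TSV readers/writers for TE/gene expression tables.

All tables are tab-delimited UTF-8 text with ``NA`` for missing values;
there is deliberately no CSV dialect and no quoting.  Feature annotations
follow a flattened repeatmasker ``name / family / class`` triple, with the
class vocabulary collapsed to the four major transposable-element types
(LINE, SINE, LTR, DNA) plus ``other`` for everything else repeatmasker
annotates (satellites, tRNAs, simple repeats, ...).

Floats are serialized with 17 significant digits so result tables
round-trip bit-exactly through the matching readers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# --- vocabulary -----------------------------------------------------------

#: The four major TE classes reported at type level.
TE_CLASSES = ("LINE", "SINE", "LTR", "DNA")
#: Catch-all class for repeat categories outside the four major types.
OTHER_TE_CLASS = "other"
VALID_TE_CLASSES = TE_CLASSES + (OTHER_TE_CLASS,)

GENE_KIND = "gene"
TE_KIND = "TE"

NA_TOKEN = "NA"
FLOAT_FORMAT = "%.17g"

ANNOTATION_COLUMNS = ("feature_id", "kind", "te_name", "te_family", "te_class")
DE_COLUMNS = ("feature_id", "base_mean", "log2fc", "se", "wald_p", "adj_p")
TYPETEST_COLUMNS = (
    "te_class",
    "n_te",
    "median_log2fc",
    "reference_mean",
    "shapiro_W",
    "shapiro_p",
    "test_mode",
    "U_or_W",
    "p_value",
    "untestable",
)
CORRELATION_COLUMNS = ("scope", "name", "r", "p", "partial", "covariates", "n")


class TableFormatError(ValueError):
    """A table violated its schema or a container invariant."""


# --- containers -----------------------------------------------------------


@dataclass
class CountMatrix:
    """Feature x sample count matrix.

    ``values`` holds nonnegative reals: integers after naive unique-read
    counting, fractional after EM assignment, arbitrary positive reals once
    normalized.  ``normalized`` distinguishes raw from size-factor-scaled
    counts; both variants share this container.
    """

    values: np.ndarray
    feature_ids: tuple
    sample_ids: tuple
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = tuple(str(f) for f in self.feature_ids)
        self.sample_ids = tuple(str(s) for s in self.sample_ids)
        if self.values.ndim != 2:
            raise TableFormatError("count matrix values must be 2-dimensional")
        nf, ns = self.values.shape
        if nf != len(self.feature_ids) or ns != len(self.sample_ids):
            raise TableFormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        for ids, what in ((self.feature_ids, "feature"), (self.sample_ids, "sample")):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise TableFormatError(f"duplicate {what} id: {dup}")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise TableFormatError("count matrix contains non-finite values")
        if self.values.size and self.values.min() < 0:
            i, j = np.argwhere(self.values < 0)[0]
            raise TableFormatError(
                f"negative count at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.feature_ids), columns=list(self.sample_ids)
        )

    def feature_index(self) -> dict:
        return {f: i for i, f in enumerate(self.feature_ids)}

    def sample_index(self) -> dict:
        return {s: i for i, s in enumerate(self.sample_ids)}

    def subset_samples(self, sample_ids) -> "CountMatrix":
        idx = self.sample_index()
        cols = [idx[s] for s in sample_ids]
        return CountMatrix(
            self.values[:, cols], self.feature_ids, tuple(sample_ids), self.normalized
        )

    def subset_features(self, feature_ids) -> "CountMatrix":
        idx = self.feature_index()
        rows = [idx[f] for f in feature_ids]
        return CountMatrix(
            self.values[rows, :], tuple(feature_ids), self.sample_ids, self.normalized
        )


@dataclass(frozen=True)
class FeatureAnnotation:
    """Annotation record for one feature: a gene or a named TE."""

    feature_id: str
    kind: str
    te_name: str = ""
    te_family: str = ""
    te_class: str = ""

    def __post_init__(self):
        if self.kind not in (GENE_KIND, TE_KIND):
            raise TableFormatError(
                f"feature {self.feature_id!r}: kind must be 'gene' or 'TE', "
                f"got {self.kind!r}"
            )
        if self.kind == TE_KIND and not self.te_class:
            raise TableFormatError(
                f"TE feature {self.feature_id!r} has no te_class"
            )
        if self.kind == GENE_KIND and (self.te_name or self.te_family or self.te_class):
            raise TableFormatError(
                f"gene feature {self.feature_id!r} must have empty TE fields"
            )
        if self.te_class and self.te_class not in VALID_TE_CLASSES:
            raise TableFormatError(
                f"feature {self.feature_id!r}: unknown te_class {self.te_class!r}"
            )


@dataclass(frozen=True)
class AlignmentRecord:
    """One read and the set of candidate features it hits.

    Multi-mapping reads (common for repeats) have ``len(hits) > 1`` and are
    the input the EM assignment stage disambiguates.
    """

    read_id: str
    hits: frozenset

    def __post_init__(self):
        object.__setattr__(self, "hits", frozenset(self.hits))
        if not self.hits:
            raise TableFormatError(f"read {self.read_id!r} has no hits")


@dataclass
class TypeTestResult:
    """Class-level location test of TE log2FCs against the global null.

    ``reference_mean`` is the mean log2 fold-change of all count-filtered
    transcripts — the location that library-wide artifacts would shift
    genes and TEs alike, hence the comparison point.  The Shapiro–Wilk
    screen is reported but never gates the rank test.
    """

    te_class: str
    n_te: int
    median_log2fc: float
    reference_mean: float
    shapiro_W: float
    shapiro_p: float
    test_mode: str
    U_or_W: float
    p_value: float
    untestable: bool = False

    def __post_init__(self):
        if not self.untestable and not (0.0 <= self.p_value <= 1.0):
            raise TableFormatError(
                f"p_value {self.p_value} outside [0, 1] for class {self.te_class}"
            )


@dataclass
class CorrelationResult:
    """Pearson (optionally partial) correlation of a TE quantity with age."""

    scope: str  # total_TE | per_class | per_TE
    name: str
    r: float
    p: float
    partial: bool
    covariates: tuple = ()
    n: int = 0

    def __post_init__(self):
        self.covariates = tuple(self.covariates)
        if abs(self.r) > 1 + 1e-12:
            raise TableFormatError(f"|r| = {abs(self.r)} exceeds 1 for {self.name!r}")


# --- internal helpers -----------------------------------------------------


def _first_duplicate(ids):
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def _read_str_table(path) -> pd.DataFrame:
    # dtype=str + keep_default_na=False: only the explicit "NA" token is
    # treated as missing, and only where a column permits it.
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _parse_float(cell: str, context: str) -> float:
    try:
        return float(cell)
    except ValueError:
        raise TableFormatError(f"non-numeric value {cell!r} at {context}") from None


def _parse_optional_float(cell: str, context: str) -> float:
    if cell == NA_TOKEN or cell == "":
        return math.nan
    return _parse_float(cell, context)


def _write_frame(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN, float_format=FLOAT_FORMAT)


# --- count matrix I/O -----------------------------------------------------


def read_count_matrix(path, normalized: bool = False) -> CountMatrix:
    """Read a feature x sample TSV: first column feature ids, header sample ids.

    Raises :class:`TableFormatError` on duplicate ids and on negative or
    non-numeric cells, naming the offending row/column.
    """
    raw = _read_str_table(path)
    if raw.shape[1] < 1:
        raise TableFormatError(f"{path}: no columns found")
    feature_ids = tuple(raw.iloc[:, 0].astype(str))
    sample_ids = tuple(str(c) for c in raw.columns[1:])
    values = np.empty((len(feature_ids), len(sample_ids)), dtype=float)
    for j, sample in enumerate(sample_ids):
        col = raw.iloc[:, j + 1]
        for i, cell in enumerate(col):
            v = _parse_float(
                cell, f"feature {feature_ids[i]!r}, sample {sample!r}"
            )
            if v < 0:
                raise TableFormatError(
                    f"negative count at feature {feature_ids[i]!r}, sample {sample!r}"
                )
            values[i, j] = v
    return CountMatrix(values, feature_ids, sample_ids, normalized=normalized)


def write_count_matrix(matrix: CountMatrix, path) -> None:
    df = matrix.to_frame()
    df.insert(0, "feature_id", list(matrix.feature_ids))
    _write_frame(df, path)


# --- annotation I/O -------------------------------------------------------

_CLASS_LOOKUP = {c.lower(): c for c in TE_CLASSES}


def normalize_te_class(raw: str) -> str:
    """Map a repeatmasker-style class string onto the fixed vocabulary.

    Matching is case-insensitive; anything outside the four major types
    (satellites, tRNAs, simple repeats, ...) maps to ``other``.
    """
    key = raw.strip()
    if not key:
        return ""
    return _CLASS_LOOKUP.get(key.lower(), OTHER_TE_CLASS)


def read_te_annotation(path) -> list:
    """Read a feature annotation TSV into :class:`FeatureAnnotation` records."""
    raw = _read_str_table(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in raw.columns]
    if missing:
        raise TableFormatError(f"{path}: missing annotation columns {missing}")
    records = []
    seen = set()
    for row in raw.itertuples(index=False):
        fid = str(row.feature_id)
        if fid in seen:
            raise TableFormatError(f"duplicate feature id: {fid}")
        seen.add(fid)
        kind = row.kind.strip()
        te_class = normalize_te_class(row.te_class)
        if kind == TE_KIND and not te_class:
            raise TableFormatError(f"TE feature {fid!r} has no te_class")
        records.append(
            FeatureAnnotation(
                feature_id=fid,
                kind=kind,
                te_name=row.te_name.strip(),
                te_family=row.te_family.strip(),
                te_class=te_class,
            )
        )
    return records


def write_te_annotation(records, path) -> None:
    df = annotation_to_frame(records)
    _write_frame(df, path)


def annotation_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.feature_id, r.kind, r.te_name, r.te_family, r.te_class)
            for r in records
        ],
        columns=list(ANNOTATION_COLUMNS),
    )


def te_ids_by_class(records, te_class=None) -> list:
    """Feature ids of TEs, optionally restricted to one class."""
    return [
        r.feature_id
        for r in records
        if r.kind == TE_KIND and (te_class is None or r.te_class == te_class)
    ]


# --- sample metadata I/O --------------------------------------------------


def read_sample_metadata(path) -> pd.DataFrame:
    """Read sample metadata (sample_id, group, age, sex, pmi, extras).

    ``age`` must be nonnegative when present; ``pmi`` and extra numeric
    covariates may carry ``NA``.
    """
    raw = _read_str_table(path)
    if "sample_id" not in raw.columns:
        raise TableFormatError(f"{path}: missing sample_id column")
    dup = _first_duplicate(list(raw["sample_id"]))
    if dup is not None:
        raise TableFormatError(f"duplicate sample id: {dup}")
    out = pd.DataFrame({"sample_id": raw["sample_id"].astype(str)})
    for col in raw.columns:
        if col == "sample_id":
            continue
        if col in ("group", "sex"):
            out[col] = raw[col].astype(str)
        else:
            out[col] = [
                _parse_optional_float(c, f"sample {sid!r}, column {col!r}")
                for sid, c in zip(out["sample_id"], raw[col])
            ]
    if "age" in out.columns:
        bad = out.loc[out["age"] < 0, "sample_id"]
        if len(bad):
            raise TableFormatError(f"negative age for sample {bad.iloc[0]!r}")
    return out


def write_sample_metadata(metadata: pd.DataFrame, path) -> None:
    _write_frame(metadata, path)


# --- alignment I/O --------------------------------------------------------


def read_alignments(path) -> list:
    """Read ``read_id TAB comma-joined-hits`` records."""
    records = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip() and header.split("\t")[0].strip() != "read_id":
            raise TableFormatError(f"{path}: expected header 'read_id\\thits'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TableFormatError(f"{path}:{lineno}: expected 2 columns")
            read_id, hits = parts
            records.append(
                AlignmentRecord(read_id, frozenset(h for h in hits.split(",") if h))
            )
    return records


def write_alignments(records, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("read_id\thits\n")
        for r in records:
            fh.write(f"{r.read_id}\t{','.join(sorted(r.hits))}\n")


# --- results I/O ----------------------------------------------------------


def validate_de_results(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"DE results missing columns {missing}")
    dup = _first_duplicate(list(df["feature_id"]))
    if dup is not None:
        raise TableFormatError(f"duplicate feature id: {dup}")
    for col, lo, hi in (("wald_p", 0, 1), ("adj_p", 0, 1)):
        vals = df[col].to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals >= lo) & (vals <= hi))
        if not ok.all():
            fid = df["feature_id"].iloc[int(np.argmin(ok))]
            raise TableFormatError(f"{col} outside [0, 1] for feature {fid!r}")
    if (df["base_mean"].to_numpy(dtype=float) < 0).any():
        raise TableFormatError("negative base_mean")
    return df.loc[:, list(DE_COLUMNS)]


def write_de_results(df: pd.DataFrame, path) -> None:
    _write_frame(validate_de_results(df), path)


def read_de_results(path) -> pd.DataFrame:
    raw = _read_str_table(path)
    missing = [c for c in DE_COLUMNS if c not in raw.columns]
    if missing:
        raise TableFormatError(f"{path}: missing DE columns {missing}")
    df = pd.DataFrame({"feature_id": raw["feature_id"].astype(str)})
    for col in DE_COLUMNS[1:]:
        df[col] = [
            _parse_optional_float(c, f"feature {fid!r}, column {col!r}")
            for fid, c in zip(df["feature_id"], raw[col])
        ]
    return validate_de_results(df)


def type_test_results_to_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            (
                r.te_class,
                r.n_te,
                r.median_log2fc,
                r.reference_mean,
                r.shapiro_W,
                r.shapiro_p,
                r.test_mode,
                r.U_or_W,
                r.p_value,
                r.untestable,
            )
        )
    return pd.DataFrame(rows, columns=list(TYPETEST_COLUMNS))


def write_type_test_results(results, path) -> None:
    _write_frame(type_test_results_to_frame(results), path)


def read_type_test_results(path) -> list:
    raw = _read_str_table(path)
    missing = [c for c in TYPETEST_COLUMNS if c not in raw.columns]
    if missing:
        raise TableFormatError(f"{path}: missing type-test columns {missing}")
    out = []
    for row in raw.itertuples(index=False):
        ctx = f"class {row.te_class!r}"
        out.append(
            TypeTestResult(
                te_class=row.te_class,
                n_te=int(row.n_te),
                median_log2fc=_parse_optional_float(row.median_log2fc, ctx),
                reference_mean=_parse_optional_float(row.reference_mean, ctx),
                shapiro_W=_parse_optional_float(row.shapiro_W, ctx),
                shapiro_p=_parse_optional_float(row.shapiro_p, ctx),
                test_mode=row.test_mode,
                U_or_W=_parse_optional_float(row.U_or_W, ctx),
                p_value=_parse_optional_float(row.p_value, ctx),
                untestable=row.untestable == "True",
            )
        )
    return out


def correlation_results_to_frame(results) -> pd.DataFrame:
    rows = [
        (r.scope, r.name, r.r, r.p, r.partial, ",".join(r.covariates), r.n)
        for r in results
    ]
    return pd.DataFrame(rows, columns=list(CORRELATION_COLUMNS))


def write_correlation_results(results, path) -> None:
    _write_frame(correlation_results_to_frame(results), path)


def read_correlation_results(path) -> list:
    raw = _read_str_table(path)
    missing = [c for c in CORRELATION_COLUMNS if c not in raw.columns]
    if missing:
        raise TableFormatError(f"{path}: missing correlation columns {missing}")
    out = []
    for row in raw.itertuples(index=False):
        ctx = f"correlation {row.name!r}"
        out.append(
            CorrelationResult(
                scope=row.scope,
                name=row.name,
                r=_parse_float(row.r, ctx),
                p=_parse_optional_float(row.p, ctx),
                partial=row.partial == "True",
                covariates=tuple(c for c in row.covariates.split(",") if c),
                n=int(row.n),
            )
        )
    return out


def write_results(results, path) -> None:
    """Dispatch writer: DE frame, TypeTestResult list, or CorrelationResult list."""
    if isinstance(results, pd.DataFrame):
        write_de_results(results, path)
        return
    results = list(results)
    if results and isinstance(results[0], CorrelationResult):
        write_correlation_results(results, path)
    else:
        write_type_test_results(results, path)
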