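"""Data model and file IO shared by all pipeline stages.

The pipeline operates on four kinds of input: an integer gene x sample count
matrix, a per-sample design/metadata table, an hourly on-site weather record,
and a gene -> functional-term annotation table. Each is wrapped in a small
validated container so downstream stages can assume consistent identifiers,
declared factor levels, and monotone timestamps.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "CountMatrix",
    "FactorDomains",
    "SampleTable",
    "HourlyWeather",
    "AnnotationMap",
    "StudyReport",
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "read_weather",
    "write_weather",
    "read_annotation",
    "write_annotation",
    "validate_study",
    "WEATHER_FEATURES",
]

#: Feature columns an hourly weather record is expected to carry. The set is
#: configurable at read time; these are the station's ten recorded variables.
WEATHER_FEATURES = (
    "temperature",
    "precipitation",
    "wind_speed",
    "relative_humidity",
    "solar_radiance",
    "radiation_density",
    "pressure",
    "dew_point",
    "ref_evapotranspiration",
    "clear_sky_radiation",
)


class ValidationError(ValueError):
    """Raised when an input file or container violates its invariants."""


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with identifier lists.

    Invariants: unique gene and sample identifiers, non-negative integer
    counts, dimensions consistent with the identifier lists.
    """

    genes: list
    samples: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.samples = list(self.samples)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            dup = _first_duplicate(self.genes)
            raise ValidationError(f"duplicate gene identifier: {dup!r}")
        if len(set(self.samples)) != len(self.samples):
            dup = _first_duplicate(self.samples)
            raise ValidationError(f"duplicate sample identifier: {dup!r}")
        if self.counts.size and not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise ValidationError("counts must be non-negative")

    @property
    def shape(self) -> tuple:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.samples)

    def subset_genes(self, genes) -> "CountMatrix":
        idx = {g: i for i, g in enumerate(self.genes)}
        rows = [idx[g] for g in genes]
        return CountMatrix(list(genes), self.samples, self.counts[rows])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CountMatrix)
            and self.genes == other.genes
            and self.samples == other.samples
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class FactorDomains:
    """Declared factor levels for the study design.

    Levels are configuration, not constants: rootstock names beyond the
    study's {ungrafted, 1103P, 3309C, SO4} are accepted by declaring them.
    """

    tissue: tuple = ("leaf", "reproductive")
    phenology: tuple = ("anthesis", "veraison", "harvest")
    rootstock: tuple = ("ungrafted", "1103P", "3309C", "SO4")
    irrigation: tuple = ("none", "rdi", "full")


DEFAULT_DOMAINS = FactorDomains()

SAMPLE_COLUMNS = (
    "sample",
    "tissue",
    "year",
    "phenology",
    "rootstock",
    "irrigation",
    "block",
    "datetime",
)


@dataclass
class SampleTable:
    """Per-sample design metadata: one row per sample, factor levels drawn
    from declared domains, parseable sampling datetime (timezone-naive local
    time; the weather clock is assumed to share it)."""

    data: pd.DataFrame
    domains: FactorDomains = field(default_factory=FactorDomains)

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        if df["sample"].duplicated().any():
            dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
            raise ValidationError(f"duplicate sample identifier: {dup!r}")
        for factor in ("tissue", "phenology", "rootstock", "irrigation"):
            levels = set(getattr(self.domains, factor))
            bad = set(df[factor].astype(str)) - levels
            if bad:
                raise ValidationError(
                    f"unknown {factor} level(s) {sorted(bad)}; declared domain {sorted(levels)}"
                )
        try:
            df["datetime"] = pd.to_datetime(df["datetime"])
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"unparseable sampling datetime: {exc}") from exc
        df["year"] = df["year"].astype(int)
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def samples(self) -> list:
        return self.data["sample"].tolist()

    def indexed(self) -> pd.DataFrame:
        return self.data.set_index("sample")


@dataclass
class HourlyWeather:
    """Hourly weather record: strictly increasing timestamps plus named
    feature columns. Gaps (missing hours) are allowed but counted."""

    data: pd.DataFrame
    units: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data.copy()
        if "timestamp" not in df.columns:
            raise ValidationError("weather table must have a 'timestamp' column")
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        ts = df["timestamp"]
        if len(ts) > 1:
            deltas = ts.diff().dropna()
            if (deltas <= pd.Timedelta(0)).any():
                i = int(np.argmax((deltas <= pd.Timedelta(0)).to_numpy()))
                raise ValidationError(
                    f"weather timestamps not strictly increasing at row {i + 1}"
                )
        self.data = df.reset_index(drop=True)

    @property
    def features(self) -> list:
        return [c for c in self.data.columns if c != "timestamp"]

    @property
    def n_gaps(self) -> int:
        """Number of missing hours implied by non-hourly spacing."""
        ts = self.data["timestamp"]
        if len(ts) < 2:
            return 0
        hours = ts.diff().dropna() / pd.Timedelta(hours=1)
        return int((hours - 1).clip(lower=0).round().sum())

    def indexed(self) -> pd.DataFrame:
        return self.data.set_index("timestamp")


@dataclass
class AnnotationMap:
    """Gene -> functional-term records with optional match E-values.

    (gene, term) pairs are unique; a missing E-value is carried as NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in ("gene", "term"):
            if col not in df.columns:
                raise ValidationError(f"annotation table missing column {col!r}")
        if "source" not in df.columns:
            df["source"] = "other"
        if "evalue" not in df.columns:
            df["evalue"] = np.nan
        df["evalue"] = pd.to_numeric(df["evalue"], errors="coerce")
        if (df["evalue"].dropna() < 0).any():
            raise ValidationError("negative E-value in annotation table")
        df = df.drop_duplicates(subset=["gene", "term"], keep="first")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def terms(self) -> list:
        return sorted(self.data["term"].unique())


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(path, format: str = "tsv") -> CountMatrix:
    """Read a count matrix from TSV (genes as rows, header = sample ids) or
    MatrixMarket coordinate format with ``<path>.genes.txt`` /
    ``<path>.samples.txt`` sidecar name files."""
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except (pd.errors.ParserError, ValueError) as exc:
            raise ValidationError(f"malformed count TSV {path}: {exc}") from exc
        return CountMatrix(df.index.tolist(), df.columns.tolist(), df.to_numpy())
    if format == "mtx":
        mat = scipy.io.mmread(str(path))
        genes = _read_lines(f"{path}.genes.txt")
        samples = _read_lines(f"{path}.samples.txt")
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        return CountMatrix(genes, samples, dense)
    raise ValueError(f"unknown count format {format!r} (expected 'tsv' or 'mtx')")


def write_counts(matrix: CountMatrix, path, format: str = "tsv") -> None:
    if format == "tsv":
        matrix.to_frame().to_csv(path, sep="\t", index_label="gene")
        return
    if format == "mtx":
        sparse = scipy.sparse.coo_matrix(matrix.counts)
        scipy.io.mmwrite(str(path), sparse, field="integer")
        _write_lines(f"{path}.genes.txt", matrix.genes)
        _write_lines(f"{path}.samples.txt", matrix.samples)
        return
    raise ValueError(f"unknown count format {format!r} (expected 'tsv' or 'mtx')")


def read_metadata(path, domains: FactorDomains = DEFAULT_DOMAINS) -> SampleTable:
    df = pd.read_csv(path, sep="\t")
    return SampleTable(df, domains=domains)


def write_metadata(meta: SampleTable, path) -> None:
    meta.data.to_csv(path, sep="\t", index=False)


def read_weather(path) -> HourlyWeather:
    df = pd.read_csv(path)
    return HourlyWeather(df)


def write_weather(weather: HourlyWeather, path) -> None:
    weather.data.to_csv(path, index=False)


def read_annotation(path) -> AnnotationMap:
    df = pd.read_csv(path, sep="\t")
    return AnnotationMap(df)


def write_annotation(ann: AnnotationMap, path) -> None:
    ann.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# study validation


@dataclass
class StudyReport:
    """Cross-check of count matrix against metadata. Pure and deterministic;
    empty design cells (e.g. the uncollected reproductive/harvest cell of the
    final year) are reported, never raised."""

    unmatched_in_counts: list
    unmatched_in_meta: list
    empty_cells: list
    imbalanced_factors: list

    @property
    def ok(self) -> bool:
        return not (
            self.unmatched_in_counts
            or self.unmatched_in_meta
            or self.empty_cells
            or self.imbalanced_factors
        )


def validate_study(matrix: CountMatrix, meta: SampleTable) -> StudyReport:
    """Report samples missing from either input, design cells with zero
    replicates, and factor-level replicate imbalance.

    Raises only when the two inputs share no samples at all.
    """
    counts_set = set(matrix.samples)
    meta_set = set(meta.samples)
    shared = counts_set & meta_set
    if not shared:
        raise ValidationError("count matrix and metadata share no samples")
    unmatched_counts = sorted(counts_set - meta_set)
    unmatched_meta = sorted(meta_set - counts_set)

    df = meta.data[meta.data["sample"].isin(shared)]
    cell_factors = ["tissue", "year", "phenology", "rootstock"]
    observed = {f: sorted(df[f].unique(), key=str) for f in cell_factors}
    present = set(map(tuple, df[cell_factors].itertuples(index=False)))
    empty = [
        dict(zip(cell_factors, cell))
        for cell in itertools.product(*(observed[f] for f in cell_factors))
        if cell not in present
    ]

    imbalanced = []
    for f in cell_factors + ["irrigation"]:
        sizes = df[f].value_counts()
        if len(sizes) > 1 and sizes.min() != sizes.max():
            imbalanced.append(f)

    return StudyReport(unmatched_counts, unmatched_meta, empty, imbalanced)


# ---------------------------------------------------------------------------


def _first_duplicate(items):
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def _read_lines(path) -> list:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _write_lines(path, items) -> None:
    with open(path, "w") as fh:
        for x in items:
            fh.write(f"{x}\n")
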