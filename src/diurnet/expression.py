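"""Expression containers, RPM normalization, filtering and standardization.

The central object is :class:`ExpressionTensor`, a gene × timepoint ×
replicate array with an explicit sampling design (:class:`DesignGrid`).
Raw sequencing data enters as a :class:`CountMatrix` (gene × sample read
counts plus per-sample metadata) and is converted to reads-per-million
(RPM).  Downstream stages (wavelet screening, correlation networks, ARX
regression) consume a replicate-collapsed :class:`SeriesMatrix`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("diurnet")

__all__ = [
    "DesignGrid",
    "CountMatrix",
    "ExpressionTensor",
    "SeriesMatrix",
    "compute_rpm",
    "filter_expressed",
    "replicate_mean",
    "zscore_genes",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

def _default_hours() -> np.ndarray:
    # two diurnal cycles sampled every 4 h at hours-of-day {2,6,10,14,18,22}
    return np.arange(2.0, 48.0, 4.0)


@dataclass(frozen=True)
class DesignGrid:
    """Sampling design: absolute sampling hours and replicate count.

    Parameters
    ----------
    hours
        Strictly increasing absolute sampling hours with constant spacing,
        e.g. 2, 6, ..., 46 for two days sampled every 4 h.
    n_reps
        Biological replicates per time point.
    """

    hours: np.ndarray = field(default_factory=_default_hours)
    n_reps: int = 3

    def __post_init__(self) -> None:
        hours = np.asarray(self.hours, dtype=float)
        object.__setattr__(self, "hours", hours)
        if hours.ndim != 1 or hours.size < 2:
            raise ValueError("hours must be a 1-d array with >= 2 points")
        diffs = np.diff(hours)
        if np.any(diffs <= 0):
            raise ValueError("hours must be strictly increasing")
        if not np.allclose(diffs, diffs[0]):
            raise ValueError("hours must be equally spaced")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    @property
    def dt(self) -> float:
        """Sampling interval in hours."""
        return float(self.hours[1] - self.hours[0])

    @property
    def n_timepoints(self) -> int:
        return int(self.hours.size)

    @property
    def hour_of_day(self) -> np.ndarray:
        return np.mod(self.hours, 24.0)

    @property
    def day(self) -> np.ndarray:
        return (self.hours // 24).astype(int) + 1


@dataclass
class CountMatrix:
    """Gene × sample read counts with sample metadata.

    ``metadata`` is a DataFrame indexed like ``samples`` with columns
    ``day`` (1-based), ``hour`` (hour of day) and ``replicate`` (1-based).
    ``library_size`` holds mapped reads per sample.
    """

    genes: list[str]
    samples: list[str]
    counts: np.ndarray
    metadata: pd.DataFrame
    library_size: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.library_size = np.asarray(self.library_size, dtype=float)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError("counts shape does not match gene/sample lists")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("counts must be integral")
        if np.any(self.library_size <= 0):
            raise ValueError("library sizes must be positive")
        required = {"day", "hour", "replicate"}
        if not required.issubset(self.metadata.columns):
            raise ValueError(f"sample metadata must contain columns {sorted(required)}")
        if list(self.metadata.index) != list(self.samples):
            raise ValueError("metadata index must match sample list")

    # -- I/O -----------------------------------------------------------------
    def to_tsv(self, counts_path, metadata_path) -> None:
        df = pd.DataFrame(self.counts, index=pd.Index(self.genes, name="gene_id"),
                          columns=self.samples)
        df.to_csv(counts_path, sep="\t")
        meta = self.metadata.copy()
        meta.insert(0, "sample_id", self.samples)
        meta["library_size"] = self.library_size
        meta.to_csv(metadata_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path, metadata_path,
                 library_from_column_sums: bool = False) -> "CountMatrix":
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(metadata_path, sep="\t").set_index("sample_id")
        meta = meta.loc[df.columns]
        if library_from_column_sums or "library_size" not in meta.columns:
            lib = df.sum(axis=0).to_numpy(dtype=float)
        else:
            lib = meta["library_size"].to_numpy(dtype=float)
        return cls(genes=list(df.index), samples=list(df.columns),
                   counts=df.to_numpy(), metadata=meta[["day", "hour", "replicate"]],
                   library_size=lib)


@dataclass
class ExpressionTensor:
    """Gene × timepoint × replicate expression values (RPM or simulated)."""

    genes: list[str]
    grid: DesignGrid
    values: np.ndarray  # shape (G, T, R)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.genes), self.grid.n_timepoints, self.grid.n_reps)
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} does not match design {expected}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def subset(self, gene_ids) -> "ExpressionTensor":
        idx = {g: i for i, g in enumerate(self.genes)}
        rows = [idx[g] for g in gene_ids]
        return ExpressionTensor(list(gene_ids), self.grid, self.values[rows])

    def sample_columns(self) -> list[str]:
        return [f"d{d}_h{h:g}_r{r}"
                for d, h in zip(self.grid.day, self.grid.hour_of_day)
                for r in range(1, self.grid.n_reps + 1)]

    def to_tsv(self, path) -> None:
        flat = self.values.reshape(self.n_genes, -1)
        pd.DataFrame(flat, index=pd.Index(self.genes, name="gene_id"),
                     columns=self.sample_columns()).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, grid: DesignGrid) -> "ExpressionTensor":
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy().reshape(len(df), grid.n_timepoints, grid.n_reps)
        return cls(list(df.index), grid, values)


@dataclass
class SeriesMatrix:
    """One series per gene on the design's time axis (replicates collapsed)."""

    genes: list[str]
    hours: np.ndarray
    values: np.ndarray  # shape (G, T)

    def __post_init__(self) -> None:
        self.hours = np.asarray(self.hours, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), self.hours.size):
            raise ValueError("values shape does not match genes × hours")
        if np.any(np.diff(self.hours) <= 0):
            raise ValueError("hours must be strictly increasing")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("missing values are not allowed")

    @property
    def dt(self) -> float:
        return float(self.hours[1] - self.hours[0])

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def subset(self, gene_ids) -> "SeriesMatrix":
        idx = {g: i for i, g in enumerate(self.genes)}
        rows = [idx[g] for g in gene_ids]
        return SeriesMatrix(list(gene_ids), self.hours, self.values[rows])

    def to_tsv(self, path) -> None:
        cols = [f"h{h:g}" for h in self.hours]
        pd.DataFrame(self.values, index=pd.Index(self.genes, name="gene_id"),
                     columns=cols).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "SeriesMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        hours = np.array([float(c.lstrip("h")) for c in df.columns])
        return cls(list(df.index), hours, df.to_numpy())


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def compute_rpm(counts: CountMatrix) -> ExpressionTensor:
    """Convert read counts to reads per million mapped reads (RPM).

    ``rpm(g, s) = count(g, s) / library_size(s) × 10⁶``.  Samples are
    arranged into the (timepoint, replicate) grid implied by the metadata;
    a duplicate or missing (day, hour, replicate) cell is an error.
    """
    meta = counts.metadata
    abs_hour = (meta["day"].to_numpy(dtype=float) - 1) * 24.0 + meta["hour"].to_numpy(dtype=float)
    hours = np.unique(abs_hour)
    reps = np.unique(meta["replicate"].to_numpy())
    n_reps = reps.size
    grid = DesignGrid(hours=hours, n_reps=int(n_reps))

    rpm = counts.counts * (1e6 / counts.library_size)[None, :]

    hour_pos = {h: i for i, h in enumerate(hours)}
    rep_pos = {r: i for i, r in enumerate(reps)}
    values = np.full((len(counts.genes), hours.size, n_reps), np.nan)
    for s, sample in enumerate(counts.samples):
        t = hour_pos[abs_hour[s]]
        r = rep_pos[meta["replicate"].iloc[s]]
        if not np.isnan(values[0, t, r]):
            raise ValueError(f"duplicate sample for timepoint/replicate cell: {sample}")
        values[:, t, r] = rpm[:, s]
    missing = np.argwhere(np.isnan(values[0]))
    if missing.size:
        t, r = missing[0]
        raise ValueError(
            f"incomplete design grid: no sample at hour {hours[t]} replicate {reps[r]}")
    return ExpressionTensor(list(counts.genes), grid, values)


def filter_expressed(tensor: ExpressionTensor, min_rpm: float = 1.0) -> list[str]:
    """Expressed-gene filter.

    A gene is kept iff at some timepoint *every* replicate reaches
    ``min_rpm`` (boundary inclusive), i.e. RPM ≥ 1 in all replicates at one
    or more sampling times under the defaults.
    """
    ok = np.any(np.all(tensor.values >= min_rpm, axis=2), axis=1)
    kept = [g for g, k in zip(tensor.genes, ok) if k]
    logger.info("filter_expressed: kept %d / %d genes at min_rpm=%g",
                len(kept), tensor.n_genes, min_rpm)
    return kept


def replicate_mean(tensor: ExpressionTensor) -> SeriesMatrix:
    """Arithmetic mean over replicates per (gene, timepoint)."""
    return SeriesMatrix(list(tensor.genes), tensor.grid.hours,
                        tensor.values.mean(axis=2))


def zscore_genes(series: SeriesMatrix, log2_transform: bool = False
                 ) -> tuple[SeriesMatrix, list[str]]:
    """Standardize each gene series to mean 0, sd 1 (population sd, ddof=0).

    With ``log2_transform`` the series is first mapped to log2(x + 1).
    Constant genes cannot be standardized; they are excluded and returned
    in the second element so the caller can report them.
    """
    values = series.values
    if log2_transform:
        values = np.log2(values + 1.0)
        logger.info("zscore_genes: applied log2(x+1) pre-transform")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    constant = (sd[:, 0] == 0)
    excluded = [g for g, c in zip(series.genes, constant) if c]
    if excluded:
        logger.warning("zscore_genes: excluded %d constant genes: %s",
                       len(excluded), excluded[:10])
    keep = ~constant
    z = (values[keep] - mean[keep]) / sd[keep]
    kept_genes = [g for g, k in zip(series.genes, keep) if k]
    return SeriesMatrix(kept_genes, series.hours, z), excluded
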