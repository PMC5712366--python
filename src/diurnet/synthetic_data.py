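"""Synthetic diurnal expression data with known ground truth.

Three generators emulate the statistical structure the analysis pipeline
assumes: genes with 24 h sinusoidal dynamics (known amplitude/phase/
baseline), background genes that are autocorrelated noise, and gene sets
coupled by a sparse stable ARX(p) system with a known adjacency.  A
Poisson count sampler inverts the RPM transform so the normalization
stage can be exercised on count-level data.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import CountMatrix, DesignGrid, ExpressionTensor

__all__ = [
    "TruthPhases",
    "TruthNetwork",
    "generate_periodic_tensor",
    "generate_nonperiodic_tensor",
    "generate_arx_tensor",
    "generate_counts",
]

BURN_IN = 100          # discarded ARX warm-up steps
MAX_SPECTRAL_RADIUS = 0.95


@dataclass
class TruthPhases:
    """Planted sinusoid parameters: per-gene amplitude, phase (h) and baseline."""

    table: pd.DataFrame  # index gene_id; columns amplitude, phase, baseline

    def __post_init__(self) -> None:
        if np.any(self.table["amplitude"] < 0):
            raise ValueError("amplitudes must be >= 0")
        if np.any((self.table["phase"] < 0) | (self.table["phase"] >= 24)):
            raise ValueError("phases must lie in [0, 24)")

    def to_tsv(self, path) -> None:
        self.table.rename_axis("gene_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "TruthPhases":
        return cls(pd.read_csv(path, sep="\t", index_col="gene_id"))


@dataclass
class TruthNetwork:
    """Planted ARX ground truth: binary adjacency (regulator → target) and
    per-lag coefficient matrices."""

    genes: list[str]
    adjacency: np.ndarray      # (G, G), adjacency[i, j] = 1 iff i -> j
    coefficients: np.ndarray   # (p, G, G), coefficients[l, j, i]: effect of i on j at lag l+1
    order: int

    def __post_init__(self) -> None:
        nz = np.any(self.coefficients != 0, axis=0).T  # -> (i, j) orientation
        np.fill_diagonal(nz, False)
        if not np.array_equal(self.adjacency.astype(bool), nz):
            raise ValueError("adjacency must mark exactly the nonzero off-diagonal coefficients")

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def edge_set(self) -> set[tuple[str, str]]:
        return {(self.genes[i], self.genes[j])
                for i, j in zip(*np.nonzero(self.adjacency))}

    def to_tsv(self, path) -> None:
        rows = []
        for lag in range(self.order):
            for j, i in zip(*np.nonzero(self.coefficients[lag])):
                rows.append((self.genes[i], self.genes[j], lag + 1,
                             self.coefficients[lag, j, i]))
        pd.DataFrame(rows, columns=["source", "target", "lag", "coefficient"]
                     ).to_csv(path, sep="\t", index=False)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_periodic_tensor(
    n_genes: int,
    grid: DesignGrid | None = None,
    amplitude_range: tuple[float, float] = (2.0, 10.0),
    noise_sd: float = 0.5,
    seed: int = 0,
    *,
    phases: np.ndarray | None = None,
    amplitudes: np.ndarray | None = None,
    baselines: np.ndarray | None = None,
    gene_prefix: str = "per",
) -> tuple[ExpressionTensor, TruthPhases]:
    """Genes following a 24 h cosine: baseline + A·cos(2π(t − φ)/24) + noise.

    Phases are uniform on [0, 24); baselines are drawn a little above the
    amplitude so the noiseless trough stays positive and the oscillation is
    a substantial fraction of the mean — the ~2-fold-or-more cycling
    typical of clock-controlled transcripts.  Explicit ``phases``/
    ``amplitudes``/``baselines`` override the random draws.  Replicates are
    independent Gaussian measurement noise around the shared latent
    trajectory.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    grid = grid or DesignGrid()
    rng = _rng(seed)
    A = (np.asarray(amplitudes, dtype=float) if amplitudes is not None
         else rng.uniform(*amplitude_range, size=n_genes))
    phi = (np.asarray(phases, dtype=float) if phases is not None
           else rng.uniform(0.0, 24.0, size=n_genes))
    base = (np.asarray(baselines, dtype=float) if baselines is not None
            else A + rng.uniform(1.0, 5.0, size=n_genes))
    if np.any(A < 0):
        raise ValueError("amplitudes must be >= 0")

    t = grid.hours
    latent = base[:, None] + A[:, None] * np.cos(2 * np.pi * (t[None, :] - phi[:, None]) / 24.0)
    noise = rng.normal(0.0, noise_sd, size=(n_genes, grid.n_timepoints, grid.n_reps))
    values = latent[:, :, None] + noise

    genes = [f"{gene_prefix}{i:05d}" for i in range(n_genes)]
    truth = TruthPhases(pd.DataFrame(
        {"amplitude": A, "phase": np.mod(phi, 24.0), "baseline": base},
        index=pd.Index(genes, name="gene_id")))
    return ExpressionTensor(genes, grid, values), truth


def generate_nonperiodic_tensor(
    n_genes: int,
    grid: DesignGrid | None = None,
    ar_coefficient: float = 0.3,
    noise_sd: float = 0.5,
    seed: int = 0,
    *,
    baseline_range: tuple[float, float] = (5.0, 20.0),
    gene_prefix: str = "bg",
) -> ExpressionTensor:
    """Background genes: baseline + AR(1) latent series + replicate noise.

    The AR(1) innovations and the replicate measurement noise both have
    standard deviation ``noise_sd``; at ``noise_sd=0`` the series degenerates
    to the constant baseline.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if abs(ar_coefficient) >= 1:
        raise ValueError("|ar_coefficient| must be < 1 (stationarity)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    grid = grid or DesignGrid()
    rng = _rng(seed)
    T = grid.n_timepoints
    base = rng.uniform(*baseline_range, size=n_genes)

    latent = np.zeros((n_genes, T + BURN_IN))
    innov = rng.normal(0.0, noise_sd, size=(n_genes, T + BURN_IN))
    for t in range(1, T + BURN_IN):
        latent[:, t] = ar_coefficient * latent[:, t - 1] + innov[:, t]
    latent = base[:, None] + latent[:, BURN_IN:]

    noise = rng.normal(0.0, noise_sd, size=(n_genes, T, grid.n_reps))
    genes = [f"{gene_prefix}{i:05d}" for i in range(n_genes)]
    return ExpressionTensor(genes, grid, latent[:, :, None] + noise)


def _companion_spectral_radius(coefs: np.ndarray) -> float:
    p, G, _ = coefs.shape
    companion = np.zeros((G * p, G * p))
    companion[:G] = np.concatenate(list(coefs), axis=1)
    if p > 1:
        companion[G:, :-G] = np.eye(G * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(companion))))


def generate_arx_tensor(
    n_genes: int,
    n_parents: int,
    children_per_parent: int,
    order: int = 1,
    coef_magnitude: tuple[float, float] = (0.4, 0.8),
    innovation_sd: float = 0.1,
    grid_or_length: DesignGrid | int | None = None,
    seed: int = 0,
    *,
    n_reps: int = 1,
    measurement_sd: float = 0.0,
    gene_prefix: str = "arx",
) -> tuple[ExpressionTensor, TruthNetwork]:
    """Simulate a sparse stable ARX(p) system with known directed edges.

    The first ``n_parents`` genes each regulate ``children_per_parent``
    distinct other genes; coefficients at every lag are drawn with magnitude
    in ``coef_magnitude`` and random sign.  Dynamics follow
    x(t) = Σ_l C_l x(t−l) + e(t) with Gaussian innovations, a burn-in of
    at least 100 discarded steps, and coefficient matrices rescaled if
    needed so the companion-matrix spectral radius is ≤ 0.95.  Replicates
    (if requested) add iid Gaussian measurement noise of sd
    ``measurement_sd`` around the shared latent trajectory.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    n_edges = n_parents * children_per_parent
    if n_edges > n_genes * n_genes - n_genes:
        raise ValueError("requested edge count exceeds available off-diagonal slots")
    if children_per_parent > n_genes - 1:
        raise ValueError("children_per_parent exceeds available targets")
    rng = _rng(seed)

    if grid_or_length is None:
        grid_or_length = DesignGrid()
    if isinstance(grid_or_length, DesignGrid):
        grid = grid_or_length
    else:
        T = int(grid_or_length)
        grid = DesignGrid(hours=np.arange(T, dtype=float) * 4.0 + 2.0, n_reps=n_reps)
    T = grid.n_timepoints

    coefs = np.zeros((order, n_genes, n_genes))  # coefs[l, target, source]
    for parent in range(n_parents):
        candidates = [g for g in range(n_genes)
                      if g != parent and not np.any(coefs[:, g, parent])]
        children = rng.choice(candidates, size=children_per_parent, replace=False)
        for child in children:
            mag = rng.uniform(*coef_magnitude, size=order)
            sign = rng.choice([-1.0, 1.0], size=order)
            coefs[:, child, parent] = mag * sign

    rho = _companion_spectral_radius(coefs)
    if rho > MAX_SPECTRAL_RADIUS:
        s = rho / MAX_SPECTRAL_RADIUS
        for lag in range(order):
            coefs[lag] /= s ** (lag + 1)

    burn = max(BURN_IN, 2 * order)
    total = T + burn
    x = np.zeros((total, n_genes))
    innov = rng.normal(0.0, innovation_sd, size=(total, n_genes))
    for t in range(total):
        x[t] = innov[t]
        for lag in range(1, order + 1):
            if t - lag >= 0:
                x[t] += coefs[lag - 1] @ x[t - lag]
    latent = x[burn:].T  # (G, T)

    if measurement_sd > 0:
        noise = rng.normal(0.0, measurement_sd, size=(n_genes, T, grid.n_reps))
        values = latent[:, :, None] + noise
    else:
        values = np.repeat(latent[:, :, None], grid.n_reps, axis=2)

    genes = [f"{gene_prefix}{i:05d}" for i in range(n_genes)]
    adjacency = np.any(coefs != 0, axis=0).T.astype(int)  # (source, target)
    np.fill_diagonal(adjacency, 0)
    truth = TruthNetwork(genes, adjacency, coefs, order)
    return ExpressionTensor(genes, grid, values), truth


def generate_counts(
    tensor: ExpressionTensor,
    library_sizes: np.ndarray | float,
    seed: int = 0,
) -> CountMatrix:
    """Poisson count sampler inverting the RPM transform.

    ``count(g, s) ~ Poisson(value(g, s) × library_size(s) / 10⁶)``.
    Negative expression values are rejected; callers that simulate noisy
    tensors clip at zero before requesting counts.
    """
    if np.any(tensor.values < 0):
        raise ValueError("expression values must be nonnegative for count generation")
    rng = _rng(seed)
    n_samples = tensor.grid.n_timepoints * tensor.grid.n_reps
    lib = np.broadcast_to(np.asarray(library_sizes, dtype=float), (n_samples,)).copy()
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")

    flat = tensor.values.reshape(tensor.n_genes, n_samples)
    counts = rng.poisson(flat * (lib / 1e6)[None, :])

    samples = tensor.sample_columns()
    meta = pd.DataFrame(
        {"day": np.repeat(tensor.grid.day, tensor.grid.n_reps),
         "hour": np.repeat(tensor.grid.hour_of_day, tensor.grid.n_reps),
         "replicate": np.tile(np.arange(1, tensor.grid.n_reps + 1),
                              tensor.grid.n_timepoints)},
        index=pd.Index(samples, name="sample_id"))
    return CountMatrix(list(tensor.genes), samples, counts, meta, lib)
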