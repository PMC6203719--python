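"""Per-data-type banks of locally scaled Gaussian kernels.

For every data type a grid of (neighbor count k, width multiplier sigma)
pairs produces a bank of patient x patient Gaussian kernels

    K(x_i, x_j) = exp(-||x_i - x_j||^2 / (2 eps_ij^2)) / (eps_ij sqrt(2 pi))

with a locally scaled bandwidth eps_ij = sigma * (mu_i + mu_j) / 2, where
mu_i is the mean Euclidean distance from patient i to its k nearest other
patients.  The default grid (k = 10, 12, ..., 30; sigma = 1.0, 1.25, 1.5,
1.75, 2.0) yields 55 kernels per data type.  Kernels built from different
data types live on heterogeneous scales, so each one is symmetrically
normalized (D^{-1/2} K D^{-1/2}) before entering the weighted combination.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .io import MultiOmicsDataset, OmicsMatrix, write_matrix  # noqa: F401  (re-export surface)

#: floor for the locally scaled bandwidth, guards duplicated samples
EPSILON_FLOOR = 1e-10

DEFAULT_NEIGHBOR_COUNTS = tuple(range(10, 31, 2))  # 11 values
DEFAULT_SIGMA_MULTIPLIERS = (1.0, 1.25, 1.5, 1.75, 2.0)  # 5 values


@dataclass(frozen=True)
class KernelGrid:
    """The (k, sigma) grid indexing one data type's kernel bank."""

    neighbor_counts: tuple[int, ...] = DEFAULT_NEIGHBOR_COUNTS
    sigma_multipliers: tuple[float, ...] = DEFAULT_SIGMA_MULTIPLIERS

    def __post_init__(self) -> None:
        object.__setattr__(self, "neighbor_counts", tuple(int(k) for k in self.neighbor_counts))
        object.__setattr__(self, "sigma_multipliers", tuple(float(s) for s in self.sigma_multipliers))
        if any(k < 1 for k in self.neighbor_counts):
            raise ValueError("all neighbor counts must be >= 1")
        if any(s <= 0 for s in self.sigma_multipliers):
            raise ValueError("all sigma multipliers must be > 0")

    @property
    def size(self) -> int:
        return len(self.neighbor_counts) * len(self.sigma_multipliers)

    def __iter__(self) -> Iterator[tuple[int, float]]:
        for k in self.neighbor_counts:
            for s in self.sigma_multipliers:
                yield k, s


@dataclass(frozen=True)
class KernelEntry:
    """One kernel matrix with its provenance."""

    data_type: str
    k: int
    sigma: float
    matrix: np.ndarray


@dataclass(frozen=True)
class KernelBank:
    """All kernels for a dataset, grouped by data type in grid order."""

    entries: tuple[KernelEntry, ...]
    n_samples: int
    data_types: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        object.__setattr__(self, "entries", entries)
        seen: list[str] = []
        for e in entries:
            if e.data_type not in seen:
                seen.append(e.data_type)
            if e.matrix.shape != (self.n_samples, self.n_samples):
                raise ValueError("kernel shape does not match sample count")
        object.__setattr__(self, "data_types", tuple(seen))

    def __len__(self) -> int:
        return len(self.entries)

    def stacked(self) -> np.ndarray:
        """All kernels as one (n_kernels, N, N) array."""
        return np.stack([e.matrix for e in self.entries])

    def per_type_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {t: 0 for t in self.data_types}
        for e in self.entries:
            counts[e.data_type] += 1
        return counts


def local_scales(m: OmicsMatrix | np.ndarray, k: int) -> np.ndarray:
    """Mean Euclidean distance from each row to its k nearest other rows.

    k is capped at N-2 (with a warning) so every sample retains at least
    one non-neighbor; fewer than 3 samples cannot be locally scaled.
    """
    values = m.values if isinstance(m, OmicsMatrix) else np.asarray(m, dtype=float)
    n = values.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 samples for local scaling, got {n}")
    if k < 1:
        raise ValueError(f"neighbor count must be >= 1, got {k}")
    k_eff = min(k, n - 2)
    if k_eff != k:
        warnings.warn(f"neighbor count {k} capped to {k_eff} for N={n}", stacklevel=2)
    dist = squareform(pdist(values))
    # column 0 of the sort is the self-distance 0; neighbors start at 1
    ordered = np.sort(dist, axis=1)
    return ordered[:, 1 : k_eff + 1].mean(axis=1)


def gaussian_kernel(
    m: OmicsMatrix | np.ndarray, k: int, sigma: float
) -> np.ndarray:
    """Locally scaled Gaussian kernel with bandwidth eps_ij = sigma*(mu_i+mu_j)/2."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    values = m.values if isinstance(m, OmicsMatrix) else np.asarray(m, dtype=float)
    mu = local_scales(values, k)
    eps = sigma * (mu[:, None] + mu[None, :]) / 2.0
    if np.any(eps < EPSILON_FLOOR):
        warnings.warn(
            "zero local scale (duplicated samples?); bandwidth floored", stacklevel=2
        )
        eps = np.maximum(eps, EPSILON_FLOOR)
    sq = squareform(pdist(values)) ** 2
    kernel = np.exp(-sq / (2.0 * eps**2)) / (eps * np.sqrt(2.0 * np.pi))
    # enforce exact symmetry against floating-point asymmetry in pdist round-trip
    return (kernel + kernel.T) / 2.0


def normalize_kernel(kernel: np.ndarray) -> np.ndarray:
    """Symmetric normalization D^{-1/2} K D^{-1/2} with D = diag(row sums)."""
    kernel = np.asarray(kernel, dtype=float)
    d = kernel.sum(axis=1)
    if np.any(d <= 0):
        raise ValueError("kernel has a non-positive row sum; entries must be positive")
    inv_sqrt = 1.0 / np.sqrt(d)
    out = kernel * inv_sqrt[:, None] * inv_sqrt[None, :]
    return (out + out.T) / 2.0


def build_bank(ds: MultiOmicsDataset, grid: KernelGrid | None = None) -> KernelBank:
    """One normalized kernel per (data type, k, sigma) grid point.

    Deterministic ordering: data types in dataset order, then grid order.
    Neighbor counts above N-2 are capped (duplicate kernels are allowed so
    the bank size stays grid-sized; the learned weights absorb redundancy).
    """
    grid = grid or KernelGrid()
    entries = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # capping warned once per bank below
        capped = any(k > ds.n_samples - 2 for k, _ in grid)
        for m in ds.matrices:
            for k, sigma in grid:
                kernel = normalize_kernel(gaussian_kernel(m, k, sigma))
                entries.append(KernelEntry(m.data_type, k, sigma, kernel))
    if capped:
        warnings.warn(
            f"neighbor counts above N-2={ds.n_samples - 2} were capped; "
            "bank retains one kernel per grid point",
            stacklevel=2,
        )
    return KernelBank(entries=tuple(entries), n_samples=ds.n_samples)


def export_bank(bank: KernelBank, directory: str | Path) -> None:
    """Cache a bank as TSV matrices plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, e in enumerate(bank.entries):
        name = f"kernel_{i:03d}.tsv"
        np.savetxt(directory / name, e.matrix, delimiter="\t")
        manifest.append({"file": name, "data_type": e.data_type, "k": e.k, "sigma": e.sigma})
    (directory / "manifest.json").write_text(
        json.dumps({"n_samples": bank.n_samples, "kernels": manifest}, indent=2)
    )


def import_bank(directory: str | Path) -> KernelBank:
    directory = Path(directory)
    meta = json.loads((directory / "manifest.json").read_text())
    entries = tuple(
        KernelEntry(
            rec["data_type"],
            int(rec["k"]),
            float(rec["sigma"]),
            np.loadtxt(directory / rec["file"], delimiter="\t"),
        )
        for rec in meta["kernels"]
    )
    return KernelBank(entries=entries, n_samples=int(meta["n_samples"]))
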