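"""Learning a block-structured patient similarity from a kernel bank.

The similarity S (N x N, rows on the probability simplex) is learned
jointly with kernel weights w (on the simplex) and a low-rank factor L
(N x C, orthonormal columns) by minimizing

    - sum_{i,j,l} w_l K_l(x_i, x_j) S_ij          (kernel alignment)
    + beta ||S||_F^2                              (spread penalty)
    + gamma tr(L^T (I_N - S) L)                   (low-rank / C-block push)
    + rho sum_l w_l log w_l                       (weight entropy)

subject to L^T L = I_C, sum_l w_l = 1, w >= 0, each row of S summing to 1
with nonnegative entries.  Each block of variables has an exact solver, so
alternating them is coordinate descent:

* S rows: the row objective is quadratic, -A_i.S_i + beta||S_i||^2
  - gamma (L L^T)_i . S_i with A = sum_l w_l K_l; its unconstrained
  minimizer is (A_i + gamma (L L^T)_i) / (2 beta), and the constrained
  minimizer is that vector's Euclidean projection onto the simplex
  (exact sort-based projection).
* L: tr(L^T (I_N - S_sym) L) under L^T L = I_C is minimized by the
  eigenvectors of the C smallest eigenvalues of the Laplacian I_N - S_sym
  (Ky Fan); the achieved trace equals the sum of those eigenvalues.
* w: -sum_l a_l w_l + rho sum_l w_l log w_l on the simplex, with
  a_l = sum_ij K_l S_ij, has the closed form w_l proportional to
  exp(a_l / rho) (softmax at temperature rho, max-subtracted).

Between S and L updates an optional graph-diffusion step sharpens the
block structure: S is propagated through its own k-nearest-neighbor
transition matrix (P S P^T), symmetrized and re-row-normalized.  The
diffusion is not a descent step, so it can be disabled to recover strict
objective monotonicity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import xlogy

from .io import MultiOmicsDataset
from .kernels import KernelBank, KernelGrid, build_bank


@dataclass(frozen=True)
class Hyperparameters:
    """Tuning knobs of the similarity optimization (all dimensionless)."""

    beta: float = 0.8        # Frobenius penalty; must be > 0
    gamma: float = 1.0       # low-rank push
    rho: float = 1.0         # weight-entropy temperature
    damping: float = 0.5     # fraction of the new S accepted per iteration
    tol: float = 1e-5        # relative Frobenius change of S at convergence
    max_iter: int = 50
    diffusion: bool = True
    k_diff: int | None = None  # default min(30, N-1)

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0 (the S sub-problem is degenerate at 0)")
        if self.gamma < 0 or self.rho <= 0:
            raise ValueError("gamma must be >= 0 and rho > 0")
        if not 0 < self.damping <= 1:
            raise ValueError("damping must be in (0, 1]")


@dataclass(frozen=True)
class SimilarityModel:
    """State of the alternating optimization."""

    S: np.ndarray                 # N x N, rows on the simplex
    L: np.ndarray                 # N x C, orthonormal columns
    w: np.ndarray                 # kernel weights on the simplex
    C: int
    params: Hyperparameters
    trace: tuple[dict, ...] = field(default_factory=tuple)
    converged: bool = True

    @property
    def S_sym(self) -> np.ndarray:
        return (self.S + self.S.T) / 2.0

    @property
    def n_samples(self) -> int:
        return self.S.shape[0]

    def validate(self, atol_rows: float = 1e-8, atol_w: float = 1e-12) -> None:
        """Assert the structural invariants; raises AssertionError on violation."""
        assert np.all(self.S >= 0)
        assert np.allclose(self.S.sum(axis=1), 1.0, atol=atol_rows)
        gram = self.L.T @ self.L
        assert np.abs(gram - np.eye(self.C)).max() <= 1e-8
        assert np.all(self.w >= 0)
        assert abs(self.w.sum() - 1.0) <= atol_w


def project_rows_to_simplex(v: np.ndarray) -> np.ndarray:
    """Exact Euclidean projection of each row onto the probability simplex.

    Sort-based algorithm: with u the row sorted descending and
    tau = (cumsum(u) - 1)/j at the largest j where u_j > (cumsum_j - 1)/j,
    the projection is max(v - tau, 0).
    """
    v = np.atleast_2d(np.asarray(v, dtype=float))
    n = v.shape[1]
    u = -np.sort(-v, axis=1)
    css = np.cumsum(u, axis=1)
    j = np.arange(1, n + 1)
    cond = u - (css - 1.0) / j > 0
    rho = n - 1 - np.argmax(cond[:, ::-1], axis=1)  # last True index per row
    tau = (css[np.arange(v.shape[0]), rho] - 1.0) / (rho + 1)
    return np.maximum(v - tau[:, None], 0.0)


def _row_normalize(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=1, keepdims=True)
    sums[sums <= 0] = 1.0
    return m / sums


def _sorted_eigvecs(sym: np.ndarray, c: int) -> tuple[np.ndarray, np.ndarray]:
    """C smallest-eigenvalue eigenvectors of a symmetric matrix, signs fixed
    so each column's largest-magnitude component is positive."""
    vals, vecs = np.linalg.eigh((sym + sym.T) / 2.0)
    vecs = vecs[:, :c].copy()
    for j in range(c):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vals[:c], vecs


def kernel_alignments(bank_stack: np.ndarray, S: np.ndarray) -> np.ndarray:
    """a_l = sum_ij K_l,ij S_ij for every kernel in the bank."""
    return np.tensordot(bank_stack, S, axes=([1, 2], [0, 1]))


def objective(
    S: np.ndarray, L: np.ndarray, w: np.ndarray, bank_stack: np.ndarray, p: Hyperparameters
) -> float:
    """The full objective value at (S, L, w)."""
    a = kernel_alignments(bank_stack, S)
    align = -float(w @ a)
    frob = p.beta * float(np.sum(S * S))
    lap = p.gamma * float(np.trace(L.T @ L) - np.sum((L @ L.T) * S))
    entropy = p.rho * float(np.sum(xlogy(w, w)))
    return align + frob + lap + entropy


def initialize(
    bank: KernelBank, C: int, params: Hyperparameters | None = None
) -> SimilarityModel:
    """Uniform kernel weights, row-normalized average kernel, spectral L."""
    params = params or Hyperparameters()
    n = bank.n_samples
    if not 2 <= C <= n - 1:
        raise ValueError(f"C={C} outside the valid range [2, {n - 1}]")
    n_kernels = len(bank)
    w = np.full(n_kernels, 1.0 / n_kernels)
    stack = bank.stacked()
    S = _row_normalize(np.tensordot(w, stack, axes=1))
    _, L = _sorted_eigvecs(np.eye(n) - (S + S.T) / 2.0, C)
    return SimilarityModel(S=S, L=L, w=w, C=C, params=params)


def update_S(model: SimilarityModel, bank: KernelBank | np.ndarray) -> SimilarityModel:
    """Row-wise exact minimization of the S sub-problem, with damping."""
    stack = bank if isinstance(bank, np.ndarray) else bank.stacked()
    p = model.params
    A = np.tensordot(model.w, stack, axes=1)
    target = (A + p.gamma * (model.L @ model.L.T)) / (2.0 * p.beta)
    S_new = project_rows_to_simplex(target)
    if p.damping < 1.0:
        S_new = p.damping * S_new + (1.0 - p.damping) * model.S
    return replace(model, S=S_new)


def update_L(model: SimilarityModel) -> SimilarityModel:
    """L <- eigenvectors of the C smallest eigenvalues of I - S_sym."""
    n = model.n_samples
    _, L = _sorted_eigvecs(np.eye(n) - model.S_sym, model.C)
    return replace(model, L=L)


def update_w(model: SimilarityModel, bank: KernelBank | np.ndarray) -> SimilarityModel:
    """Entropy-regularized closed form: softmax of alignments at temperature rho."""
    stack = bank if isinstance(bank, np.ndarray) else bank.stacked()
    a = kernel_alignments(stack, model.S) / model.params.rho
    a -= a.max()
    w = np.exp(a)
    w /= w.sum()
    return replace(model, w=w)


def diffusion_enhance(model: SimilarityModel, k_diff: int | None = None) -> SimilarityModel:
    """One step of kNN-graph diffusion: S <- rownorm(sym(P S P^T)).

    P is S with each row restricted to its k_diff largest entries (the
    diagonal always kept) and re-normalized.  Diffusion concentrates mass
    inside well-connected blocks and never creates support across exact
    blocks.
    """
    n = model.n_samples
    if k_diff is None:
        k_diff = min(30, n - 1)
    if k_diff < 1:
        raise ValueError(f"k_diff must be >= 1, got {k_diff}")
    k_eff = min(k_diff, n - 1)
    S = model.S
    keep = np.zeros_like(S, dtype=bool)
    # top-k entries per row; argpartition is O(N) per row
    idx = np.argpartition(-S, kth=k_eff - 1, axis=1)[:, :k_eff]
    np.put_along_axis(keep, idx, True, axis=1)
    keep[np.arange(n), np.arange(n)] = True
    P = _row_normalize(np.where(keep, S, 0.0))
    T = P @ S @ P.T
    S_new = _row_normalize((T + T.T) / 2.0)
    return replace(model, S=S_new)


def fit(
    ds: MultiOmicsDataset,
    C: int,
    params: Hyperparameters | None = None,
    grid: KernelGrid | None = None,
) -> SimilarityModel:
    """Build the kernel bank for a dataset and run the optimization."""
    bank = build_bank(ds, grid)
    return fit_bank(bank, C, params)


def fit_bank(
    bank: KernelBank, C: int, params: Hyperparameters | None = None
) -> SimilarityModel:
    """Alternating optimization until the similarity stabilizes.

    Iterates update_S -> diffusion (optional) -> update_L -> update_w
    until the relative Frobenius change of S drops below ``tol`` or
    ``max_iter`` is reached; on non-convergence the best iterate so far is
    returned with ``converged=False`` and a warning, never an exception.
    The trace records the objective after every sub-step.
    """
    params = params or Hyperparameters()
    model = initialize(bank, C, params)
    stack = bank.stacked()
    trace: list[dict] = []
    converged = False
    for it in range(params.max_iter):
        S_prev = model.S
        model = update_S(model, stack)
        obj_s = objective(model.S, model.L, model.w, stack, params)
        if params.diffusion:
            model = diffusion_enhance(model, params.k_diff)
        model = update_L(model)
        obj_l = objective(model.S, model.L, model.w, stack, params)
        model = update_w(model, stack)
        obj_w = objective(model.S, model.L, model.w, stack, params)
        denom = np.linalg.norm(S_prev)
        s_change = float(np.linalg.norm(model.S - S_prev) / denom) if denom else 0.0
        trace.append(
            {
                "iteration": it,
                "objective_after_S": obj_s,
                "objective_after_L": obj_l,
                "objective": obj_w,
                "s_change": s_change,
            }
        )
        if s_change < params.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"similarity optimization did not converge in {params.max_iter} iterations "
            f"(last relative change {trace[-1]['s_change']:.3g}); returning last iterate",
            stacklevel=2,
        )
    return replace(model, trace=tuple(trace), converged=converged)


def export_similarity(model: SimilarityModel, bank: KernelBank, directory) -> None:
    """Write S_sym, kernel weights and the convergence trace to disk."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / "similarity_sym.tsv", model.S_sym, delimiter="\t")
    with open(directory / "kernel_weights.tsv", "w") as fh:
        fh.write("data_type\tk\tsigma\tweight\n")
        for e, weight in zip(bank.entries, model.w):
            fh.write(f"{e.data_type}\t{e.k}\t{e.sigma}\t{weight:.10g}\n")
    (directory / "trace.json").write_text(json.dumps(list(model.trace), indent=2))
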