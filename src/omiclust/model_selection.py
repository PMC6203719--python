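"""Choosing the number of clusters by a rotation-based separation cost.

For a candidate count C, take X (N x C), the eigenvectors of the C
smallest eigenvalues of the similarity Laplacian I - S_sym.  If the
similarity has C well-separated blocks, some rotation R of X makes every
row close to one-hot.  The separation cost

    J(R) = sum_ij Z_ij^2 / M_i^2,   Z = X R,   M_i = max_j |Z_ij|

is minimized over rotations (a product of C(C-1)/2 Givens rotations,
optimized by gradient descent with backtracking from several restarts).
J >= N always, with equality exactly when every row of Z has a single
nonzero entry.  Scanning C over a candidate range and taking the largest
drop J(C-1) - J(C) selects the number of clusters; remaining positive
local maxima of the drop sequence are reported as secondary peaks.

The per-row maximum is taken in magnitude: eigenvector and rotation signs
are arbitrary, and the squared form is what yields the J >= N bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

_M_FLOOR = 1e-300  # guards an exactly zero row, which orthonormal X cannot have


@dataclass(frozen=True)
class RotationSearchConfig:
    """Gradient-descent settings for the Givens-angle search."""

    n_restarts: int = 5          # random restarts in addition to the identity start
    n_iter: int = 200
    step: float = 0.1            # initial step, shrunk by backtracking
    grad_tol: float = 1e-10
    seed: int = 0


@dataclass(frozen=True)
class SeparationScan:
    """Minimized separation costs over a candidate range."""

    candidates: tuple[int, ...]
    costs: tuple[float, ...]
    drops: tuple[float, ...]     # drops[i] = costs[i] - costs[i+1], len = len(candidates)-1
    best_C: int
    secondary_peaks: tuple[int, ...]


def candidate_range(n: int) -> list[int]:
    """Candidate cluster counts: 2..15 for cohorts of >= 150 samples,
    else 2..floor(N/10)."""
    if n < 20:
        raise ValueError(f"cohort too small for a cluster-number scan (N={n} < 20)")
    upper = 15 if n >= 150 else n // 10
    if upper < 2:
        raise ValueError(f"cohort too small: floor(N/10) = {upper} < 2")
    return list(range(2, upper + 1))


def laplacian_eigvecs(S_sym: np.ndarray, c: int) -> np.ndarray:
    """Orthonormal eigenvectors of the C smallest eigenvalues of I - S_sym,
    with each column's largest-magnitude component forced positive."""
    from .similarity import _sorted_eigvecs

    n = S_sym.shape[0]
    _, vecs = _sorted_eigvecs(np.eye(n) - S_sym, c)
    return vecs


def rotation_cost(Z: np.ndarray) -> float:
    """J = sum_ij Z_ij^2 / max_j Z_ij^2, the alignment-to-one-hot cost."""
    m2 = np.maximum((Z * Z).max(axis=1), _M_FLOOR)
    return float(((Z * Z) / m2[:, None]).sum())


def _givens_pairs(c: int) -> list[tuple[int, int]]:
    return [(p, q) for p in range(c - 1) for q in range(p + 1, c)]


def _build_rotations(theta: np.ndarray, pairs: list[tuple[int, int]], c: int):
    """Per-angle Givens matrices plus prefix/suffix products.

    Returns (R, prefix, suffix) with prefix[k] = G_0 ... G_{k-1} and
    suffix[k] = G_k ... G_{K-1}, so R = prefix[K] = suffix[0].
    """
    k_angles = len(pairs)
    gs = []
    for t, (p, q) in zip(theta, pairs):
        g = np.eye(c)
        ct, st = np.cos(t), np.sin(t)
        g[p, p] = ct
        g[q, q] = ct
        g[p, q] = -st
        g[q, p] = st
        gs.append(g)
    prefix = [np.eye(c)]
    for g in gs:
        prefix.append(prefix[-1] @ g)
    suffix = [np.eye(c)] * (k_angles + 1)
    for k in range(k_angles - 1, -1, -1):
        suffix[k] = gs[k] @ suffix[k + 1]
    return prefix[-1], prefix, suffix


def _cost_and_grad(
    X: np.ndarray, theta: np.ndarray, pairs: list[tuple[int, int]]
) -> tuple[float, np.ndarray]:
    """J and its exact gradient in the Givens angles.

    With Z = X R, dJ/dZ has rows 2 Z_ij / M_i^2 off the per-row max and
    2 Z_ij* (1 - J_i) / M_i^2 at the max entry j*.  Then dJ/dtheta_k =
    <X^T dJ/dZ, U_{k-1} G'_k V_{k+1}> where U/V are prefix/suffix products
    and G'_k has only a 2x2 nonzero block, so each angle costs O(C^2).
    """
    c = X.shape[1]
    r, prefix, suffix = _build_rotations(theta, pairs, c)
    z = X @ r
    z2 = z * z
    jstar = np.argmax(z2, axis=1)
    m2 = np.maximum(z2[np.arange(z.shape[0]), jstar], _M_FLOOR)
    row_j = z2.sum(axis=1) / m2
    cost = float(row_j.sum())
    dz = 2.0 * z / m2[:, None]
    rows = np.arange(z.shape[0])
    dz[rows, jstar] = 2.0 * z[rows, jstar] * (1.0 - row_j) / m2
    p_mat = X.T @ dz  # C x C
    grad = np.empty(len(pairs))
    for k, ((p, q), t) in enumerate(zip(pairs, theta)):
        ct, st = np.cos(t), np.sin(t)
        dg = np.array([[-st, -ct], [ct, -st]])
        u2 = prefix[k][:, (p, q)]          # C x 2
        v2 = suffix[k + 1][(p, q), :]      # 2 x C
        w = (u2 @ dg) @ v2
        grad[k] = float(np.sum(p_mat * w))
    return cost, grad


def min_rotation_cost(
    X: np.ndarray,
    config: RotationSearchConfig | None = None,
    extra_starts: Sequence[np.ndarray] = (),
) -> tuple[float, np.ndarray, np.ndarray]:
    """Minimize J over rotations of X's columns; returns (J, R, angles).

    Gradient descent with backtracking on the Givens angles, from the
    identity, ``n_restarts`` seeded random starts and any caller-supplied
    warm starts; the best minimum found is returned.  For C = 1 there is
    nothing to rotate and J = N.
    """
    config = config or RotationSearchConfig()
    X = np.asarray(X, dtype=float)
    n, c = X.shape
    if c == 1:
        return float(n), np.eye(1), np.zeros(0)
    pairs = _givens_pairs(c)
    k_angles = len(pairs)
    rng = np.random.default_rng(config.seed)
    starts = [np.zeros(k_angles)]
    for warm in extra_starts:
        if len(warm) == k_angles:
            starts.append(np.asarray(warm, dtype=float))
    for _ in range(config.n_restarts):
        starts.append(rng.uniform(-np.pi / 4, np.pi / 4, size=k_angles))
    best_cost = np.inf
    best_theta = starts[0]
    for theta in starts:
        theta = theta.copy()
        cost, grad = _cost_and_grad(X, theta, pairs)
        step = config.step
        for _ in range(config.n_iter):
            gnorm = float(np.linalg.norm(grad))
            if gnorm < config.grad_tol or step < 1e-14:
                break
            # backtracking line search along -grad
            while step >= 1e-14:
                cand = theta - step * grad
                c_new, g_new = _cost_and_grad(X, cand, pairs)
                if c_new < cost:
                    theta, cost, grad = cand, c_new, g_new
                    step = min(step * 1.5, 1.0)
                    break
                step /= 2.0
        if cost < best_cost:
            best_cost, best_theta = cost, theta
    r, _, _ = _build_rotations(best_theta, pairs, c)
    return best_cost, r, best_theta


def _extend_angles(theta: np.ndarray, c_old: int, c_new: int) -> np.ndarray:
    """Embed a (c_old)-dimensional Givens solution into c_new dimensions.

    New angles (pairs touching the added coordinates) start at zero; in
    the p-major pair ordering the relative order of the old pairs is
    preserved, so the embedded product equals diag(R_old, I).
    """
    old_pairs = {pq: t for pq, t in zip(_givens_pairs(c_old), theta)}
    return np.array([old_pairs.get(pq, 0.0) for pq in _givens_pairs(c_new)])


def _angles_from_rotation(r: np.ndarray) -> np.ndarray:
    """Factor an SO(C) matrix into p-major Givens angles.

    Peels one coordinate at a time: the first C-1 angles are the
    spherical coordinates mapping e_0 to the first column of R; the
    residual is block-diagonal with an SO(C-1) tail, recursively
    factored.  Round-trips with ``_build_rotations`` to machine
    precision.
    """
    r = np.asarray(r, dtype=float).copy()
    c = r.shape[0]
    angles: list[float] = []
    for p in range(c - 1):
        v = r[p:, p]  # unit vector in the remaining coordinates
        block = len(v)
        theta = np.zeros(block - 1)
        # spherical solve: v_q = sin(t_q) prod_{q'>q} cos(t_{q'}), v_0 = prod cos
        residual = 1.0
        for q in range(block - 1, 1, -1):
            s = 0.0 if residual < 1e-300 else float(np.clip(v[q] / residual, -1.0, 1.0))
            t = float(np.arcsin(s))
            theta[q - 1] = t
            residual *= np.cos(t)
        theta[0] = float(np.arctan2(v[1], v[0]))  # full-range angle fixes v_0's sign
        angles.extend(theta)
        # undo the rotation on the remaining block
        sub_pairs = _givens_pairs(block)[: block - 1]
        g = np.eye(block)
        for t, (pp, qq) in zip(theta, sub_pairs):
            gk = np.eye(block)
            ct, st = np.cos(t), np.sin(t)
            gk[pp, pp] = ct
            gk[qq, qq] = ct
            gk[pp, qq] = -st
            gk[qq, pp] = st
            g = g @ gk
        r[p:, p:] = g.T @ r[p:, p:]
    return np.array(angles)


def scan(
    S_sym: np.ndarray,
    candidates: list[int] | tuple[int, ...],
    config: RotationSearchConfig | None = None,
) -> SeparationScan:
    """Minimized J per candidate C; the largest drop selects best_C.

    drops[i] = J(candidates[i]) - J(candidates[i+1]); each candidate's
    rotation search is warm-started from the previous candidate's
    solution (embedded with zero angles on the new coordinate) in
    addition to the usual restarts.  When the scan starts at C = 2 the
    degenerate single-cluster cost J(1) = N anchors a leading drop
    N - J(2), so a two-block similarity (where J(2) attains the bound N)
    can select the first candidate.  best_C is the candidate after the
    largest drop; other positive local maxima of the drop sequence are
    reported as secondary peaks in descending drop order.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate list is empty")
    if candidates != sorted(candidates):
        raise ValueError("candidates must be ascending")
    n = S_sym.shape[0]
    eigvecs = {c: laplacian_eigvecs(S_sym, c) for c in candidates}
    costs: list[float] = []
    thetas: list[np.ndarray] = []
    prev: tuple[int, np.ndarray] | None = None
    for c in candidates:
        warm = [_extend_angles(prev[1], prev[0], c)] if prev else []
        j, _, theta = min_rotation_cost(eigvecs[c], config, extra_starts=warm)
        costs.append(j)
        thetas.append(theta)
        prev = (c, theta)
    # backward polish: seed each candidate from the next one's rotation,
    # truncated and projected back onto SO(C); suppresses optimizer noise
    # that would otherwise fake small drops in the rising tail of J
    polish = RotationSearchConfig(
        n_restarts=0, n_iter=(config or RotationSearchConfig()).n_iter,
        step=(config or RotationSearchConfig()).step, seed=0,
    )
    for i in range(len(candidates) - 2, -1, -1):
        c1, c2 = candidates[i], candidates[i + 1]
        if c1 < 2:
            continue
        r2, _, _ = _build_rotations(thetas[i + 1], _givens_pairs(c2), c2)
        u, _, vt = np.linalg.svd(r2[:c1, :c1])
        r1 = u @ vt
        if np.linalg.det(r1) < 0:
            u[:, -1] *= -1
            r1 = u @ vt
        back = _angles_from_rotation(r1)
        j, _, theta = min_rotation_cost(
            eigvecs[c1], polish, extra_starts=[thetas[i], back]
        )
        if j < costs[i]:
            costs[i] = j
            thetas[i] = theta
    return select_from_costs(candidates, costs, n)


def select_from_costs(
    candidates: Sequence[int], costs: Sequence[float], n: int
) -> SeparationScan:
    """Largest-drop selection (and secondary peaks) from a J-vs-C curve.

    When the candidate list opens at C = 2, the degenerate J(1) = N
    anchors a leading drop N - J(2) so the first candidate is selectable;
    it wins exactly when J(2) attains the bound N and no real drop is
    positive.
    """
    candidates = list(candidates)
    costs = [float(c) for c in costs]
    if len(candidates) != len(costs):
        raise ValueError("candidates and costs must align")
    if len(candidates) == 1:
        return SeparationScan(
            candidates=tuple(candidates),
            costs=tuple(costs),
            drops=(),
            best_C=candidates[0],
            secondary_peaks=(),
        )
    drops = [costs[i] - costs[i + 1] for i in range(len(costs) - 1)]
    lead = [float(n) - costs[0]] if candidates[0] == 2 else []
    all_drops = lead + drops
    drop_candidates = (candidates if lead else candidates[1:])
    best_i = int(np.argmax(all_drops))
    best_c = drop_candidates[best_i]
    peaks = []
    for i, d in enumerate(all_drops):
        if i == best_i or d <= 0:
            continue
        left = all_drops[i - 1] if i > 0 else -np.inf
        right = all_drops[i + 1] if i < len(all_drops) - 1 else -np.inf
        if d >= left and d >= right:
            peaks.append((d, drop_candidates[i]))
    peaks.sort(key=lambda t: -t[0])
    return SeparationScan(
        candidates=tuple(candidates),
        costs=tuple(costs),
        drops=tuple(drops),
        best_C=best_c,
        secondary_peaks=tuple(c for _, c in peaks),
    )
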