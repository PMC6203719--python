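"""Subtype assignment from a learned similarity, plus cluster-quality metrics.

The similarity is reduced to an N x C spectral embedding (eigenvectors of
the C smallest eigenvalues of I - S_sym, optionally row-normalized) and
clustered by best-of-restarts k-means.  Quality is reported as the mean
silhouette on the similarity-derived dissimilarity, the stability of
repeated k-means runs (mean pairwise NMI), and the fraction of total
kernel weight contributed by each data type.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import normalized_mutual_info_score, silhouette_samples

from .kernels import KernelBank
from .model_selection import laplacian_eigvecs
from .similarity import SimilarityModel


@dataclass(frozen=True)
class ClusterResult:
    """Labels (1..C) with the embedding and quality metrics."""

    labels: np.ndarray
    embedding: np.ndarray
    silhouette_per_sample: np.ndarray
    silhouette_mean: float
    stability_nmi: float
    seed: int


def embed(model: SimilarityModel | np.ndarray, C: int | None = None, row_normalize: bool = True) -> np.ndarray:
    """Spectral embedding of the learned similarity.

    Rows are length-normalized by default so that patients in the same
    block land on the same point of the unit sphere regardless of block
    size.
    """
    if isinstance(model, SimilarityModel):
        s_sym = model.S_sym
        C = model.C if C is None else C
    else:
        s_sym = np.asarray(model, dtype=float)
        if C is None:
            raise ValueError("C is required when passing a raw similarity matrix")
    x = laplacian_eigvecs(s_sym, C)
    if row_normalize:
        norms = np.linalg.norm(x, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        x = x / norms
    return x


def kmeans_assign(
    embedding: np.ndarray, C: int, restarts: int = 100, seed: int = 0
) -> np.ndarray:
    """Best-of-restarts k-means labels in 1..C (lowest inertia wins)."""
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    km = KMeans(n_clusters=C, n_init=restarts, random_state=seed)
    return km.fit_predict(np.asarray(embedding, dtype=float)) + 1


def similarity_dissimilarity(S_sym: np.ndarray) -> np.ndarray:
    """d_ij = 1 - S_ij / max(S), diagonal forced to zero."""
    s = np.asarray(S_sym, dtype=float)
    top = s.max()
    if top <= 0:
        raise ValueError("similarity matrix has no positive entries")
    d = 1.0 - s / top
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def silhouette_score_similarity(
    S_sym: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-sample silhouettes and their mean on the similarity-derived
    dissimilarity.  Singleton-cluster members get silhouette 0 (standard
    convention); a single cluster overall is an error."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    d = similarity_dissimilarity(S_sym)
    per_sample = silhouette_samples(d, labels, metric="precomputed")
    return per_sample, float(per_sample.mean())


def stability_nmi(
    embedding: np.ndarray, C: int, reps: int = 10, seed: int = 0, restarts: int = 1
) -> float:
    """Mean pairwise NMI (max-entropy normalization) across ``reps``
    independently seeded k-means runs on the same embedding.

    Each repetition is a single k-means initialization so the score
    probes the stability of the clustering landscape; best-of-restarts
    repetitions would trivially agree."""
    if reps < 2:
        raise ValueError("stability needs at least 2 repetitions")
    child_seeds = np.random.SeedSequence(seed).generate_state(reps)
    runs = [
        kmeans_assign(embedding, C, restarts=restarts, seed=int(s % (2**31)))
        for s in child_seeds
    ]
    scores = [
        normalized_mutual_info_score(a, b, average_method="max")
        for a, b in combinations(runs, 2)
    ]
    return float(np.mean(scores))


def weight_contributions(w: np.ndarray, bank: KernelBank) -> dict[str, float]:
    """Fraction of total kernel weight contributed by each data type."""
    w = np.asarray(w, dtype=float)
    if len(w) != len(bank):
        raise ValueError("weight vector length does not match the bank")
    out = {t: 0.0 for t in bank.data_types}
    for entry, weight in zip(bank.entries, w):
        out[entry.data_type] += float(weight)
    return out


def assign(
    model: SimilarityModel,
    C: int | None = None,
    restarts: int = 100,
    seed: int = 0,
    stability_reps: int = 10,
) -> ClusterResult:
    """Full assignment: embed, k-means, silhouette and stability."""
    C = model.C if C is None else C
    x = embed(model, C)
    labels = kmeans_assign(x, C, restarts=restarts, seed=seed)
    sil, sil_mean = silhouette_score_similarity(model.S_sym, labels)
    stab = stability_nmi(x, C, reps=stability_reps, seed=seed)
    return ClusterResult(
        labels=labels,
        embedding=x,
        silhouette_per_sample=sil,
        silhouette_mean=sil_mean,
        stability_nmi=stab,
        seed=seed,
    )
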