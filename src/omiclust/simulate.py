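"""Seeded generator of multi-omic cohorts with planted subtype structure.

The generator emulates the four data types the subtyping pipeline
consumes, with a fraction of "informative" genes per data type carrying a
cluster-specific signal:

* mutations -- Bernoulli draws; informative genes act as drivers with an
  elevated rate (background + effect) in one assigned cluster;
* copy number -- Gaussian log2-ratio noise plus a signed segment-like
  shift (+/- effect) for informative genes in their cluster;
* methylation -- Beta-distributed beta-values (fixed concentration) whose
  mean shifts from the 0.4 baseline by +effect in the assigned cluster;
* expression -- Gaussian z-scores with a signed mean shift.

Survival times are exponential with per-cluster hazards and independent
exponential censoring tuned to the requested censoring fraction.  All
draws flow from a single seed; Gaussian noise is drawn before shifts are
added and Bernoulli/Beta draws go through shared uniforms, so cohorts
generated at different effect sizes from the same seed share their noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import beta as beta_dist

from .io import (
    MultiOmicsDataset,
    OmicsMatrix,
    align_samples,
    preprocess,
    write_matrix,
)
from .stats import SurvivalRecord, write_clinical

MUTATION_BACKGROUND_RATE = 0.05
METHYLATION_BASELINE_MEAN = 0.4
METHYLATION_CONCENTRATION = 10.0

DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "mutation": 0.55,      # driver rate 0.6 against the 0.05 background
    "cna": 2.0,            # log2-ratio shift
    "methylation": 0.3,    # beta-value mean shift
    "expression": 2.0,     # z-score shift
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of a synthetic cohort."""

    n_samples: int = 150
    c_true: int = 3
    proportions: tuple[float, ...] = (0.4, 0.35, 0.25)
    genes_per_type: Mapping[str, int] = field(
        default_factory=lambda: {
            "mutation": 200, "cna": 200, "methylation": 200, "expression": 200
        }
    )
    informative_fraction: float = 0.1
    effect_size: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES)
    )
    noise_sd: float = 1.0
    survival_hazards: tuple[float, ...] = (0.0005, 0.001, 0.002)  # events/day
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "proportions", tuple(float(p) for p in self.proportions))
        object.__setattr__(self, "genes_per_type", dict(self.genes_per_type))
        object.__setattr__(self, "effect_size", dict(self.effect_size))
        object.__setattr__(self, "survival_hazards", tuple(self.survival_hazards))
        if len(self.proportions) != self.c_true:
            raise ValueError("proportions length must equal c_true")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        if any(p <= 0 for p in self.proportions):
            raise ValueError("all cluster proportions must be positive")
        if self.n_samples < self.c_true:
            raise ValueError("need at least one sample per cluster")
        if any(m < 1 for m in self.genes_per_type.values()):
            raise ValueError("genes_per_type entries must be positive")
        if not 0 <= self.informative_fraction <= 1:
            raise ValueError("informative_fraction must lie in [0, 1]")
        if any(e < 0 for e in self.effect_size.values()):
            raise ValueError("effect sizes must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if len(self.survival_hazards) != self.c_true:
            raise ValueError("one survival hazard per cluster required")
        if any(h <= 0 for h in self.survival_hazards):
            raise ValueError("hazards must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort: preprocessed dataset, raw matrices, truth."""

    dataset: MultiOmicsDataset
    true_labels: np.ndarray                  # 1..C_true, aligned with dataset rows
    survival: tuple[SurvivalRecord, ...]
    raw_matrices: tuple[OmicsMatrix, ...]    # un-normalized, for discretization

    def __iter__(self):
        # tuple-style unpacking: (dataset, labels, survival records)
        return iter((self.dataset, self.true_labels, self.survival))


def _planted_labels(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Cluster labels 1..C with expected sizes N * proportions (every
    cluster guaranteed non-empty)."""
    counts = np.floor(np.asarray(spec.proportions) * spec.n_samples).astype(int)
    counts = np.maximum(counts, 1)
    while counts.sum() < spec.n_samples:
        counts[int(np.argmax(np.asarray(spec.proportions) - counts / spec.n_samples))] += 1
    while counts.sum() > spec.n_samples:
        counts[int(np.argmax(counts))] -= 1
    labels = np.repeat(np.arange(1, spec.c_true + 1), counts)
    rng.shuffle(labels)
    return labels


def _informative_assignment(
    n_genes: int, fraction: float, c_true: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Which genes are informative, which cluster each marks, and a sign.

    Deterministic round-robin over clusters and alternating signs, so the
    planted structure depends only on the spec, not the noise stream.
    """
    n_informative = int(round(n_genes * fraction))
    genes = np.arange(n_informative)
    clusters = genes % c_true + 1
    signs = np.where(genes % 2 == 0, 1.0, -1.0)
    return genes, clusters, signs


def generate(spec: SyntheticSpec) -> SyntheticCohort:
    """Draw one cohort; bit-reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    labels = _planted_labels(spec, rng)
    sample_ids = tuple(f"P{i:04d}" for i in range(n))

    raw: list[OmicsMatrix] = []
    for data_type in ("mutation", "cna", "methylation", "expression"):
        if data_type not in spec.genes_per_type:
            continue
        m_genes = spec.genes_per_type[data_type]
        effect = spec.effect_size.get(data_type, 0.0)
        genes, gene_clusters, signs = _informative_assignment(
            m_genes, spec.informative_fraction, spec.c_true
        )
        feature_ids = tuple(f"{data_type[:3].upper()}{g:04d}" for g in range(m_genes))
        marks = np.zeros((n, m_genes))   # +/-1 where (patient, gene) carries signal
        for g, cluster, sign in zip(genes, gene_clusters, signs):
            marks[labels == cluster, g] = sign

        if data_type == "mutation":
            u = rng.random((n, m_genes))
            rates = np.where(
                marks != 0,
                np.minimum(MUTATION_BACKGROUND_RATE + effect, 0.95),
                MUTATION_BACKGROUND_RATE,
            )
            values = (u < rates).astype(float)
        elif data_type == "methylation":
            u = np.clip(rng.random((n, m_genes)), 1e-12, 1 - 1e-12)
            means = np.clip(
                METHYLATION_BASELINE_MEAN + np.abs(marks) * effect, 0.02, 0.98
            )
            a = means * METHYLATION_CONCENTRATION
            b = (1.0 - means) * METHYLATION_CONCENTRATION
            values = beta_dist.ppf(u, a, b)
            values = np.clip(values, 1e-9, 1 - 1e-9)
        else:  # cna, expression: Gaussian noise plus signed shift
            values = rng.normal(0.0, spec.noise_sd, size=(n, m_genes))
            values = values + marks * effect
        raw.append(
            OmicsMatrix(sample_ids, feature_ids, values, data_type=data_type)
        )

    dataset = align_samples([preprocess(m) for m in raw])
    # align_samples orders patients lexicographically; P#### ids are already sorted
    survival = _survival_records(spec, labels, sample_ids, rng)
    return SyntheticCohort(
        dataset=dataset,
        true_labels=labels,
        survival=tuple(survival),
        raw_matrices=tuple(raw),
    )


def _survival_records(
    spec: SyntheticSpec,
    labels: np.ndarray,
    sample_ids: Sequence[str],
    rng: np.random.Generator,
) -> list[SurvivalRecord]:
    hazards = np.asarray(spec.survival_hazards)[labels - 1]
    event_times = rng.exponential(1.0 / hazards)
    if spec.censoring_rate > 0:
        # independent exponential censoring with P(censored) = censoring_rate
        cens_rate = hazards * spec.censoring_rate / (1.0 - spec.censoring_rate)
        cens_times = rng.exponential(1.0 / cens_rate)
    else:
        cens_times = np.full_like(event_times, np.inf)
    times = np.minimum(event_times, cens_times)
    events = event_times <= cens_times
    ages = rng.uniform(40.0, 75.0, size=len(labels))
    return [
        SurvivalRecord(
            patient_id=str(pid),
            time=float(t),
            event=bool(e),
            age_at_start=float(a),
            metric="OS",
        )
        for pid, t, e, a in zip(sample_ids, times, events, ages)
    ]


def separation_ladder(
    base: SyntheticSpec, effect_multipliers: Sequence[float]
) -> list[SyntheticCohort]:
    """Cohorts identical except for a global multiplier on every planted
    effect size; the shared seed keeps labels and (where the distribution
    family allows) noise draws common across rungs."""
    multipliers = list(effect_multipliers)
    if multipliers != sorted(multipliers):
        raise ValueError("effect multipliers must be ascending")
    cohorts = []
    for mult in multipliers:
        scaled = {t: v * mult for t, v in base.effect_size.items()}
        cohorts.append(generate(replace(base, effect_size=scaled)))
    return cohorts


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write the cohort in the dialects `omiclust.io` reads.

    Mutations go out as a MAF-lite table (Hugo_Symbol, Tumor_Sample_Barcode,
    one row per mutated patient-gene pair); the other data types as raw
    TSV matrices; survival as a clinical TSV; true labels for reference.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for m in cohort.raw_matrices:
        if m.data_type == "mutation":
            path = directory / "mutations.maf"
            with open(path, "w") as fh:
                fh.write("Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\n")
                for i, sid in enumerate(m.sample_ids):
                    for j, gene in enumerate(m.feature_ids):
                        if m.values[i, j] == 1:
                            fh.write(f"{gene}\t{sid}\tMissense_Mutation\n")
            paths["mutation"] = path
        else:
            path = directory / f"{m.data_type}.tsv"
            write_matrix(m, path)
            paths[m.data_type] = path
    clinical = directory / "clinical.tsv"
    write_clinical(list(cohort.survival), clinical)
    paths["clinical"] = clinical
    truth = directory / "true_labels.tsv"
    with open(truth, "w") as fh:
        fh.write("patient_id\tcluster\n")
        for sid, lab in zip(cohort.dataset.sample_ids, cohort.true_labels):
            fh.write(f"{sid}\t{int(lab)}\n")
    paths["true_labels"] = truth
    return paths
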