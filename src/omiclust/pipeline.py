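"""End-to-end orchestration: matrices -> similarity -> subtypes -> reports.

The pipeline composes the library modules in the order the method
prescribes: ingest and normalize the per-data-type matrices, build the
Gaussian kernel banks, optionally scan for the number of clusters on the
initialized similarity, fit the block-structured similarity at the chosen
C, assign subtypes by spectral embedding + k-means, and (when clinical
data is available) run the survival separation and cluster-enrichment
analyses.  A single master seed fans out deterministically to every
stochastic sub-step, and every output file lands in a MANIFEST with its
SHA-256 checksum so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import clustering, io, model_selection, similarity, stats
from .kernels import KernelBank, KernelGrid, build_bank

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run."""

    inputs: Mapping[str, str]                  # data_type -> matrix path (TSV; MAF for mutation)
    output_dir: str
    clinical: str | None = None
    clusters: int | str = "auto"
    params: similarity.Hyperparameters = field(default_factory=similarity.Hyperparameters)
    grid: KernelGrid = field(default_factory=KernelGrid)
    seed: int = 0
    kmeans_restarts: int = 100
    stability_reps: int = 10
    enrichment: bool = True

    def __post_init__(self) -> None:
        if not self.inputs:
            raise ValueError("at least one data type input is required")
        if isinstance(self.clusters, str) and self.clusters != "auto":
            raise ValueError("clusters must be an integer or 'auto'")


@dataclass(frozen=True)
class PipelineResult:
    """In-memory artifacts of a pipeline run."""

    model: similarity.SimilarityModel
    bank: KernelBank
    scan: model_selection.SeparationScan | None
    clusters: clustering.ClusterResult
    contributions: dict[str, float]
    survival: dict | None = None
    enrichment: pd.DataFrame | None = None


def _child_seeds(seed: int, n: int = 4) -> list[int]:
    """Deterministic sub-seeds below 2**31 from one master seed."""
    return [int(s % (2**31)) for s in np.random.SeedSequence(seed).generate_state(n)]


def subtype_pipeline(
    dataset: io.MultiOmicsDataset,
    clusters: int | str = "auto",
    params: similarity.Hyperparameters | None = None,
    grid: KernelGrid | None = None,
    seed: int = 0,
    kmeans_restarts: int = 100,
    stability_reps: int = 10,
    raw_matrices: Sequence[io.OmicsMatrix] | None = None,
    survival_records: Sequence[stats.SurvivalRecord] | None = None,
    enrichment: bool = True,
) -> PipelineResult:
    """Run the full method on an in-memory dataset.

    With ``clusters="auto"`` the separation-cost scan runs on the
    initialized similarity (uniform-weight kernel average) sharpened by
    one diffusion pass, and the alternating optimization then fits at the
    selected C.
    """
    params = params or similarity.Hyperparameters()
    rotation_seed, kmeans_seed, stability_seed, _ = _child_seeds(seed)
    bank = build_bank(dataset, grid)
    scan_result = None
    if clusters == "auto":
        candidates = model_selection.candidate_range(dataset.n_samples)
        probe = similarity.initialize(bank, C=max(2, min(3, dataset.n_samples - 1)), params=params)
        probe = similarity.diffusion_enhance(probe, params.k_diff)
        scan_result = model_selection.scan(
            probe.S_sym,
            candidates,
            model_selection.RotationSearchConfig(seed=rotation_seed),
        )
        chosen_c = scan_result.best_C
        logger.info("separation-cost scan selected C=%d", chosen_c)
    else:
        chosen_c = int(clusters)
    model = similarity.fit_bank(bank, chosen_c, params)
    cluster_result = clustering.assign(
        model,
        chosen_c,
        restarts=kmeans_restarts,
        seed=kmeans_seed,
        stability_reps=stability_reps,
    )
    contributions = clustering.weight_contributions(model.w, bank)
    survival_result = None
    if survival_records is not None:
        ordered = _order_records(survival_records, dataset.sample_ids)
        if ordered is None:
            logger.warning("clinical records do not cover the cohort; survival stage skipped")
        else:
            survival_result = stats.survival_separation(cluster_result.labels, ordered)
    enrichment_result = None
    if enrichment and raw_matrices:
        enrichment_result = stats.enrichment_table(raw_matrices, cluster_result.labels)
    return PipelineResult(
        model=model,
        bank=bank,
        scan=scan_result,
        clusters=cluster_result,
        contributions=contributions,
        survival=survival_result,
        enrichment=enrichment_result,
    )


def _order_records(
    records: Sequence[stats.SurvivalRecord], sample_ids: Sequence[str]
) -> list[stats.SurvivalRecord] | None:
    by_id = {r.patient_id: r for r in records}
    if not all(s in by_id for s in sample_ids):
        return None
    return [by_id[s] for s in sample_ids]


def run(config: RunConfig) -> PipelineResult:
    """File-driven run: read inputs, execute the pipeline, write artifacts.

    Partial outputs are retained on failure, with the MANIFEST noting the
    stage that failed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    status = {"complete": False, "failed_stage": None}
    try:
        raw = _read_inputs(config)
        dataset = io.align_samples([io.preprocess(m) for m in raw])
        raw_aligned = _restrict_raw(raw, dataset.sample_ids)
        records = None
        if config.clinical:
            clinical_path = Path(config.clinical)
            if clinical_path.exists():
                records = stats.read_clinical(clinical_path)
            else:
                logger.warning("clinical file %s missing; survival stage skipped", clinical_path)
        result = subtype_pipeline(
            dataset,
            clusters=config.clusters,
            params=config.params,
            grid=config.grid,
            seed=config.seed,
            kmeans_restarts=config.kmeans_restarts,
            stability_reps=config.stability_reps,
            raw_matrices=raw_aligned,
            survival_records=records,
            enrichment=config.enrichment,
        )
        _write_artifacts(result, dataset, out, manifest)
        status["complete"] = True
        return result
    except Exception as exc:  # noqa: BLE001 - stage-tagged reporting
        status["failed_stage"] = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        _write_manifest(out, manifest, status)


def _read_inputs(config: RunConfig) -> list[io.OmicsMatrix]:
    matrices = []
    for data_type in io.DATA_TYPES:
        path = config.inputs.get(data_type)
        if path is None:
            continue
        if data_type == "mutation" and str(path).endswith((".maf", ".maf.txt")):
            universe = _maf_universe(config, path)
            matrices.append(io.read_maf(path, universe))
        else:
            matrices.append(io.read_matrix(path, data_type))
    if not matrices:
        raise ValueError("no input matrices could be read from the config")
    return matrices


def _maf_universe(config: RunConfig, maf_path: str) -> list[str]:
    """Sample universe for a MAF: patients of the other matrices if any,
    else the barcodes present in the MAF itself."""
    others = [p for t, p in config.inputs.items() if t != "mutation"]
    if others:
        ids: set[str] | None = None
        for p in others:
            cols = pd.read_csv(p, sep="\t", usecols=[0], dtype=str).iloc[:, 0]
            ids = set(cols) if ids is None else ids & set(cols)
        return sorted(ids or set())
    barcodes = pd.read_csv(maf_path, sep="\t", comment="#", dtype=str)["Tumor_Sample_Barcode"]
    return sorted(set(barcodes))


def _restrict_raw(
    raw: Sequence[io.OmicsMatrix], sample_ids: Sequence[str]
) -> list[io.OmicsMatrix]:
    from dataclasses import replace

    out = []
    for m in raw:
        idx = [m.sample_ids.index(s) for s in sample_ids]
        out.append(replace(m, sample_ids=tuple(sample_ids), values=m.values[idx]))
    return out


def _write_artifacts(
    result: PipelineResult,
    dataset: io.MultiOmicsDataset,
    out: Path,
    manifest: dict[str, str],
) -> None:
    ids = list(dataset.sample_ids)

    def save_frame(df: pd.DataFrame, name: str, **kwargs) -> None:
        path = out / name
        df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, **kwargs)
        manifest[name] = _sha256(path)

    def save_json(obj, name: str) -> None:
        path = out / name
        path.write_text(json.dumps(obj, indent=2, sort_keys=True))
        manifest[name] = _sha256(path)

    save_frame(
        pd.DataFrame(result.model.S_sym, index=ids, columns=ids),
        "similarity_sym.tsv", index_label="patient_id",
    )
    weights = pd.DataFrame(
        {
            "data_type": [e.data_type for e in result.bank.entries],
            "k": [e.k for e in result.bank.entries],
            "sigma": [e.sigma for e in result.bank.entries],
            "weight": result.model.w,
        }
    )
    save_frame(weights, "kernel_weights.tsv", index=False)
    save_frame(
        pd.DataFrame({"patient_id": ids, "cluster": result.clusters.labels}),
        "labels.tsv", index=False,
    )
    if result.scan is not None:
        save_json(
            {
                "candidates": list(result.scan.candidates),
                "costs": list(result.scan.costs),
                "drops": list(result.scan.drops),
                "best_C": result.scan.best_C,
                "secondary_peaks": list(result.scan.secondary_peaks),
            },
            "scan.json",
        )
    save_json(
        {
            "n_samples": dataset.n_samples,
            "n_clusters": int(result.model.C),
            "silhouette_mean": result.clusters.silhouette_mean,
            "stability_nmi": result.clusters.stability_nmi,
            "kernel_weight_contributions": result.contributions,
            "converged": result.model.converged,
            "n_iterations": len(result.model.trace),
        },
        "metrics.json",
    )
    if result.survival is not None:
        save_json(
            {
                "chi2": result.survival["chi2"],
                "df": result.survival["df"],
                "p_value": result.survival["p_value"],
                "n_used": result.survival["n_used"],
            },
            "logrank.json",
        )
        curves = []
        for cluster, curve in result.survival["curves"].items():
            frame = curve.to_frame()
            frame.insert(0, "cluster", cluster)
            curves.append(frame)
        save_frame(pd.concat(curves, ignore_index=True), "km_curves.tsv", index=False)
    if result.enrichment is not None:
        save_frame(result.enrichment, "enrichment.tsv", index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out: Path, manifest: dict[str, str], status: dict) -> None:
    lines = [f"# complete: {status['complete']}"]
    if status["failed_stage"]:
        lines.append(f"# failed: {status['failed_stage']}")
    for name in sorted(manifest):
        lines.append(f"{manifest[name]}  {name}")
    (out / "MANIFEST").write_text("\n".join(lines) + "\n")
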