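"""Standard-format I/O and the end-to-end pipeline.

Volumes are NIfTI-1 with 64-bit float payloads in an RAS-assumed grid;
tables are UTF-8 TSV with header rows; run configuration is YAML/JSON;
every pipeline run writes a manifest with parameters, seeds, package
versions and per-output SHA-256 checksums so reruns are verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genecorr import GENE_SET, correlate, correlation_matrix, fractional_expression
from .grids import ElementMap, Geometry
from .maps import absolute_contribution, interpolate_to_elements, region_aggregate
from .modelselect import SelectionReport, evaluate_configs
from .occmodel import FitOptions, FitResult, ModelConfig, get_config, named_configs
from .preprocess import (
    ClusterSet,
    OccupancyDataset,
    build_valid_mask,
    compute_occupancy,
    define_clusters,
    intersubject_stats,
    pool_occupancy,
    smooth_map,
)
from .synth import (
    StudyDesign,
    make_design,
    make_gene_expression,
    make_geometry,
    make_ground_truth,
    simulate_study,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# NIfTI volumes


def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])


def save_volume(path: Path, data: np.ndarray, voxel_size_mm: float) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(voxel_size_mm))
    nib.save(img, str(path))


def load_volume(path: Path) -> tuple[np.ndarray, float]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float64)
    except Exception as exc:  # malformed file
        raise ValueError(f"could not parse NIfTI volume {path}: {exc}") from exc
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0]):
        raise ValueError(f"{path}: anisotropic voxels {zooms} are not supported")
    return data, float(zooms[0])


def save_map(path: Path, emap: ElementMap) -> None:
    save_volume(path, emap.data, emap.geometry.voxel_size_mm)


def load_map(path: Path, geometry: Geometry, mask: np.ndarray | None = None) -> ElementMap:
    data, vox = load_volume(path)
    if tuple(data.shape) != tuple(geometry.shape):
        raise ValueError(
            f"{path}: volume shape {data.shape} does not match geometry {geometry.shape}"
        )
    return ElementMap(geometry, data, mask if mask is not None else geometry.mask.copy())


def save_geometry(outdir: Path, geometry: Geometry) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vox = geometry.voxel_size_mm
    save_volume(outdir / "regions.nii.gz", geometry.regions.astype(float), vox)
    save_volume(outdir / "hemispheres.nii.gz", geometry.hemispheres.astype(float), vox)
    save_volume(outdir / "mask.nii.gz", geometry.mask.astype(float), vox)


def load_geometry(indir: Path) -> Geometry:
    indir = Path(indir)
    regions, vox = load_volume(indir / "regions.nii.gz")
    hemis, _ = load_volume(indir / "hemispheres.nii.gz")
    mask, _ = load_volume(indir / "mask.nii.gz")
    return Geometry(
        tuple(regions.shape), vox, np.rint(regions).astype(np.int32),
        np.rint(hemis).astype(np.int8), mask > 0.5,
    )


# ---------------------------------------------------------------------------
# Tables


def write_design(path: Path, design: StudyDesign) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_design(path: Path) -> StudyDesign:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"design table not found: {path}")
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in StudyDesign.REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: design table is missing column(s) {missing}")
    return StudyDesign(table)


def write_expression(path: Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t")


def read_expression(path: Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression table not found: {path}")
    table = pd.read_csv(path, sep="\t")
    if "region" not in table.columns:
        raise ValueError(f"{path}: expression table is missing column 'region'")
    return table.set_index("region")


def write_occupancy_dataset(outdir: Path, dataset: OccupancyDataset) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    occ = pd.DataFrame(
        dataset.occupancy, columns=dataset.design.table["subject"].tolist()
    )
    occ.index.name = "cluster"
    occ.to_csv(outdir / "occupancy.tsv", sep="\t")
    write_design(outdir / "occasions.tsv", dataset.design)
    cl = dataset.clusters
    table = pd.DataFrame(
        {
            "cluster": np.arange(cl.n_clusters),
            "bx": cl.block_index[:, 0], "by": cl.block_index[:, 1], "bz": cl.block_index[:, 2],
            "cx_mm": cl.centroids_mm[:, 0], "cy_mm": cl.centroids_mm[:, 1],
            "cz_mm": cl.centroids_mm[:, 2], "n_elements": cl.sizes,
        }
    )
    table.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    save_volume(outdir / "cluster_labels.nii.gz", cl.labels.astype(float), cl.geometry.voxel_size_mm)
    (outdir / "block.json").write_text(json.dumps({"block": list(cl.block)}))


def read_occupancy_dataset(indir: Path, geometry: Geometry) -> OccupancyDataset:
    indir = Path(indir)
    occ = pd.read_csv(indir / "occupancy.tsv", sep="\t", index_col="cluster")
    design = read_design(indir / "occasions.tsv")
    table = pd.read_csv(indir / "clusters.tsv", sep="\t")
    labels, _ = load_volume(indir / "cluster_labels.nii.gz")
    block = tuple(json.loads((indir / "block.json").read_text())["block"])
    clusters = ClusterSet(
        geometry,
        np.rint(labels).astype(np.int32),
        table[["cx_mm", "cy_mm", "cz_mm"]].to_numpy(),
        block,
        table[["bx", "by", "bz"]].to_numpy(dtype=int),
        table["n_elements"].to_numpy(),
    )
    return OccupancyDataset(occ.to_numpy(dtype=float), clusters, design)


def write_fit_result(outdir: Path, fit: FitResult) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for drug, kis in fit.ki.items():
        for comp, ki in kis.items():
            lo, hi = fit.ki_ci[drug][comp]
            rows.append({"drug": drug, "component": comp, "ki": ki, "ci95_lo": lo, "ci95_hi": hi})
    pd.DataFrame(rows).to_csv(outdir / "global_parameters.tsv", sep="\t", index=False)
    n = fit.config.n_components
    frac = pd.DataFrame(fit.fractions, columns=[f"f_C{k + 1}" for k in range(n)])
    for k in range(n - 1):
        frac[f"v{k + 1}"] = fit.v[:, k]
    frac.index.name = "cluster"
    frac.to_csv(outdir / "cluster_fractions.tsv", sep="\t")
    summary = {
        "config": fit.config.name,
        "n_components": n,
        "displaceable": {d: list(c) for d, c in fit.config.displaceable.items()},
        "ssr": fit.ssr, "n_obs": fit.n_obs, "n_par": fit.n_par,
        "converged": fit.converged, "n_iter": fit.n_iter,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))


def write_selection_report(outdir: Path, report: SelectionReport) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metrics = report.metrics_table()
    payload = {
        "selected": report.selected,
        "alpha": report.alpha,
        "warnings": report.warnings,
        "metrics": json.loads(metrics.to_json(orient="index")),
        "f_tests": json.loads(report.f_table.to_json(orient="records")),
    }
    (outdir / "selection.json").write_text(json.dumps(payload, indent=2))
    with open(outdir / "selection.txt", "w") as fh:
        fh.write(f"selected configuration: {report.selected}\n\n")
        fh.write(metrics.to_string())
        fh.write("\n\npairwise F-tests\n")
        fh.write(report.f_table.to_string(index=False))
        fh.write("\n")


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class PipelineConfig:
    """Everything needed for a reproducible end-to-end run."""

    outdir: str = "fmzdecomp_run"
    seed: int = 0
    # simulation (used when simulate=True; otherwise read from paths)
    simulate: bool = True
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: float = 1.0
    n_regions_per_hemisphere: int = 4
    n_components: int = 3
    n_subjects_a: int = 8
    n_subjects_b: int = 4
    exposure_range: tuple[float, float] = (0.1, 120.0)
    noise_sd_occ: float = 0.05
    baseline_cv: float = 0.23
    expression_noise_sd: float = 0.05
    # inputs for non-simulated runs
    maps_dir: str | None = None
    design_path: str | None = None
    atlas_dir: str | None = None
    expression_path: str | None = None
    # preprocessing
    threshold: float = 0.1
    block: tuple[int, int, int] = (4, 4, 4)
    fwhm_mm: float = 0.0
    # model selection
    candidates: tuple[str, ...] = ("M2a", "M3c")
    alpha: float = 0.05
    with_cv: bool = True

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        for key in ("grid_shape", "block", "candidates", "exposure_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _resolve_candidates(names: tuple[str, ...]) -> list[ModelConfig]:
    from .occmodel import enumerate_configs

    by_name = dict(named_configs())
    by_name.update({c.name: c for c in enumerate_configs()})
    out = []
    for name in names:
        if name not in by_name:
            raise ValueError(f"unknown candidate configuration '{name}'")
        out.append(by_name[name])
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate -> occupancy -> fit/select -> maps -> correlate.

    Returns the manifest (also written to ``<outdir>/manifest.json``).
    Any stage failure is re-raised annotated with the stage name.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # ---- simulate or load inputs
        stage = "simulate" if config.simulate else "load"
        if config.simulate:
            geometry = make_geometry(
                config.grid_shape, config.voxel_size_mm,
                config.n_regions_per_hemisphere, seed=config.seed,
            )
            truth = make_ground_truth(geometry, config.n_components, seed=config.seed + 1)
            design = make_design(
                config.n_subjects_a, config.n_subjects_b, config.exposure_range,
                seed=config.seed + 2,
            )
            baselines, posts = simulate_study(
                truth, design, config.noise_sd_occ, config.baseline_cv, seed=config.seed + 3
            )
            expression = make_gene_expression(
                truth, geometry, noise_sd=config.expression_noise_sd, seed=config.seed + 4
            )
            save_geometry(out / "geometry", geometry)
            write_design(out / "design.tsv", design)
            write_expression(out / "expression.tsv", expression)
            mdir = out / "maps_in"
            mdir.mkdir(exist_ok=True)
            for m, row in zip(baselines, design.table.itertuples()):
                save_map(mdir / f"baseline_{row.subject}.nii.gz", m)
            for m, row in zip(posts, design.table.itertuples()):
                save_map(mdir / f"post_{row.subject}.nii.gz", m)
        else:
            if config.atlas_dir is None or config.design_path is None or config.maps_dir is None:
                raise ValueError("non-simulated runs need maps_dir, design_path and atlas_dir")
            geometry = load_geometry(Path(config.atlas_dir))
            design = read_design(Path(config.design_path))
            mdir = Path(config.maps_dir)
            baselines = [
                load_map(mdir / f"baseline_{s}.nii.gz", geometry)
                for s in design.table["subject"]
            ]
            posts = [
                load_map(mdir / f"post_{s}.nii.gz", geometry) for s in design.table["subject"]
            ]
            expression = None
            if config.expression_path is not None:
                epath = Path(config.expression_path)
                if not epath.exists():
                    raise FileNotFoundError(f"expression table not found: {epath}")
                expression = read_expression(epath)

        # ---- occupancy preprocessing
        stage = "occupancy"
        if config.fwhm_mm > 0:
            baselines = [smooth_map(m, config.fwhm_mm) for m in baselines]
            posts = [smooth_map(m, config.fwhm_mm) for m in posts]
        min_map, mean_map = intersubject_stats(baselines)
        valid = build_valid_mask(min_map, config.threshold, geometry.mask)
        occ_maps = [
            compute_occupancy(
                ElementMap(geometry, b.data, valid.mask.copy()),
                ElementMap(geometry, p.data, valid.mask.copy()),
            )
            for b, p in zip(baselines, posts)
        ]
        clusters = define_clusters(geometry, config.block, valid.mask)
        dataset = pool_occupancy(occ_maps, clusters, design)
        write_occupancy_dataset(out / "occupancy", dataset)
        save_map(out / "mean_baseline.nii.gz", mean_map)

        # ---- fit candidates and select
        stage = "fit/select"
        candidates = _resolve_candidates(config.candidates)
        report = evaluate_configs(
            candidates, dataset, geometry, alpha=config.alpha, with_cv=config.with_cv,
            options=FitOptions(seed=config.seed),
        )
        write_selection_report(out / "selection", report)
        best = next(r for r in report.configs if r.config.name == report.selected)
        write_fit_result(out / "fit", best.fit)

        # ---- component maps
        stage = "maps"
        nearest = interpolate_to_elements(best.fit, clusters, mode="nearest")
        linear = interpolate_to_elements(best.fit, clusters, mode="linear")
        mean_on_valid = ElementMap(geometry, mean_map.data, valid.mask.copy())
        absolute = absolute_contribution(linear, mean_on_valid)
        mdir2 = out / "component_maps"
        mdir2.mkdir(exist_ok=True)
        for k in range(best.fit.config.n_components):
            save_map(mdir2 / f"fraction_C{k + 1}_nearest.nii.gz", nearest.fraction_map(k + 1))
            save_map(mdir2 / f"fraction_C{k + 1}_linear.nii.gz", linear.fraction_map(k + 1))
            save_map(mdir2 / f"absolute_C{k + 1}.nii.gz", absolute.fraction_map(k + 1))
        region_table = region_aggregate(nearest, geometry)
        region_table.to_csv(out / "regional_fractions.tsv", sep="\t", index=False)

        # ---- gene-expression correlation
        stage = "correlate"
        corr_path = None
        if expression is not None:
            frac_expr = fractional_expression(expression, [g for g in GENE_SET if g in expression])
            comp_cols = [c for c in region_table.columns if c.startswith("C")]
            comp_table = region_table.set_index("region")[comp_cols]
            corr = correlate(comp_table, frac_expr)
            corr.to_csv(out / "correlations.tsv", sep="\t", index=False)
            correlation_matrix(corr).to_csv(out / "correlation_matrix.tsv", sep="\t")
            corr_path = out / "correlations.tsv"

        # ---- manifest
        stage = "manifest"
        outputs = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "parameters": _jsonable(asdict(config)),
            "selected_config": report.selected,
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
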