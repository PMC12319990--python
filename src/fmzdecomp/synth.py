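"""Synthetic ground truth for the occupancy decomposition pipeline.

The generator emulates the statistical structure the analysis assumes:
spatially smooth per-voxel fractional binding components that sum to one
and are exactly hemisphere-symmetric, a positive baseline binding
potential field in a cortical-like range, a two-arm blocking study whose
plasma exposures span the occupancy curves, additive Gaussian noise on
the occupancy scale, and a region-level gene-expression table in which
one gene tracks each binding component.

Default study conditions: 12 subjects split 8 (drug A) / 4 (drug B),
true inhibition constants K_i of (1.0, 12.0) for drug A's two
displaceable components and 1.5 for drug B's single component (a
12-fold affinity separation for drug A), occupancy-scale noise SD 0.05,
and per-element inter-subject baseline variability of 23% CV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import LEFT, RIGHT, ElementMap, Geometry
from .occmodel import M3C, ModelConfig

# Nominal single-oral-dose menus (mg) for the two drug arms.
DOSE_MENU = {"A": (0.2, 1.0, 2.0, 5.0, 20.0, 30.0), "B": (5.0, 12.0, 20.0, 30.0, 40.0)}

#: Default true inhibition constants, exposure units (drug A components
#: differ 12-fold in affinity; component 1 is shared with drug B).
DEFAULT_KI_TRUE: Mapping[str, Mapping[int, float]] = {"A": {1: 1.0, 2: 12.0}, "B": {1: 1.5}}

DEFAULT_NOISE_SD_OCC = 0.05
DEFAULT_BASELINE_CV = 0.23
DEFAULT_GENES = ("GABRA1", "GABRA2", "GABRA5", "GABRA3")


@dataclass
class GroundTruth:
    """True component fields and global parameters behind a simulation."""

    geometry: Geometry
    config: ModelConfig
    fractions: np.ndarray  # (N, nx, ny, nz), simplex per voxel
    baseline: np.ndarray  # (nx, ny, nz), BP_ND > 0
    ki: Mapping[str, Mapping[int, float]]
    gene_scale: float = 100.0

    @property
    def n_components(self) -> int:
        return self.config.n_components

    def baseline_map(self) -> ElementMap:
        return ElementMap(self.geometry, self.baseline)

    def fraction_map(self, component: int) -> ElementMap:
        """Fractional contribution field of 1-based component index."""
        return ElementMap(self.geometry, self.fractions[component - 1])


@dataclass
class StudyDesign:
    """One row per PET pretreatment occasion (one occasion per subject)."""

    table: pd.DataFrame

    REQUIRED = ("subject", "drug", "dose_mg", "exposure")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"design table is missing required column '{col}'")
        if self.table["subject"].duplicated().any():
            dup = self.table.loc[self.table["subject"].duplicated(), "subject"].iloc[0]
            raise ValueError(f"subject '{dup}' appears in more than one occasion/arm")
        if (self.table["exposure"] <= 0).any():
            raise ValueError("plasma exposures must be strictly positive")

    @property
    def n_occasions(self) -> int:
        return len(self.table)

    @property
    def drugs(self) -> list[str]:
        return sorted(self.table["drug"].unique())

    def subjects_in_arm(self, drug: str) -> list[str]:
        return list(self.table.loc[self.table["drug"] == drug, "subject"])

    @property
    def exposures(self) -> np.ndarray:
        return self.table["exposure"].to_numpy(dtype=float)

    @property
    def drug_labels(self) -> np.ndarray:
        return self.table["drug"].to_numpy()

    def subset(self, keep: np.ndarray) -> "StudyDesign":
        return StudyDesign(self.table.iloc[keep].reset_index(drop=True))


def _smooth_unit_field(rng: np.random.Generator, shape, sigma_vox: float) -> np.ndarray:
    """Smoothed white noise rescaled to zero mean, unit variance."""
    g = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox, mode="nearest")
    return (g - g.mean()) / max(g.std(), 1e-12)


def _mirror_x(arr: np.ndarray) -> np.ndarray:
    """Copy the left half onto the right half, reflected."""
    nx = arr.shape[0]
    half = nx // 2
    out = arr.copy()
    out[half:] = out[half - 1 :: -1]
    return out


def make_geometry(
    shape: tuple[int, int, int] = (16, 16, 16),
    voxel_size_mm: float = 1.0,
    n_regions_per_hemisphere: int = 4,
    seed: int = 0,
) -> Geometry:
    """Build a mirror-symmetric labeled grid with Voronoi-style regions.

    Region seeds are drawn in the left hemisphere and every voxel takes
    the label of its nearest seed; the labeling is then reflected onto
    the right hemisphere, so each region code occurs once per side with
    exactly mirrored voxel sets.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 8 for s in shape):
        raise ValueError(f"grid shape must be 3D with all dims >= 8, got {shape}")
    if shape[0] % 2:
        raise ValueError(f"mirror axis (x) has odd dimension {shape[0]}")
    if n_regions_per_hemisphere < 2:
        raise ValueError("need at least 2 regions per hemisphere")

    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    half = nx // 2
    seeds = rng.uniform((0, 0, 0), (half, ny, nz), size=(n_regions_per_hemisphere, 3))

    ix, iy, iz = np.meshgrid(
        np.arange(half) + 0.5, np.arange(ny) + 0.5, np.arange(nz) + 0.5, indexing="ij"
    )
    pts = np.stack([ix, iy, iz], axis=-1)  # (half, ny, nz, 3)
    d2 = ((pts[..., None, :] - seeds) ** 2).sum(-1)
    left_labels = d2.argmin(-1).astype(np.int32) + 1

    regions = np.zeros(shape, dtype=np.int32)
    regions[:half] = left_labels
    regions = _mirror_x(regions)

    hemispheres = np.full(shape, RIGHT, dtype=np.int8)
    hemispheres[:half] = LEFT

    mask = np.ones(shape, dtype=bool)
    return Geometry(shape, float(voxel_size_mm), regions, hemispheres, mask)


def make_ground_truth(
    geometry: Geometry,
    n_components: int = 3,
    smoothness_mm: float = 4.0,
    seed: int = 0,
    config: ModelConfig | None = None,
    ki_true: Mapping[str, Mapping[int, float]] | None = None,
    contrast: float = 1.5,
) -> GroundTruth:
    """Generate smooth, mirrored, simplex-valued component fields.

    Each component starts from an independent Gaussian random field
    smoothed to ``smoothness_mm`` FWHM-like scale; a softmax across
    components (gain ``contrast``) maps them onto the simplex.  The left
    hemisphere is reflected onto the right so the truth is exactly
    symmetric.  The baseline BP_ND field is an independent smooth field
    rescaled into a cortical-like 1-6 range.
    """
    if not 2 <= n_components <= 4:
        raise ValueError(f"n_components must be in [2, 4], got {n_components}")
    if config is None:
        config = M3C if n_components == 3 else _default_config(n_components)
    if config.n_components != n_components:
        raise ValueError("config component count does not match n_components")
    if ki_true is None:
        ki_true = _default_ki(config)
    for drug, comps in config.displaceable.items():
        missing = [k for k in comps if k not in ki_true.get(drug, {})]
        if missing:
            raise ValueError(f"true K_i missing for drug {drug} components {missing}")
        if any(v <= 0 for v in ki_true[drug].values()):
            raise ValueError("true K_i values must be positive")

    rng = np.random.default_rng(seed)
    sigma_vox = smoothness_mm / geometry.voxel_size_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    fields = np.stack(
        [_smooth_unit_field(rng, geometry.shape, sigma_vox) for _ in range(n_components)]
    )
    fields = np.stack([_mirror_x(f) for f in fields])
    z = contrast * fields
    z -= z.max(0, keepdims=True)
    ez = np.exp(z)
    fractions = ez / ez.sum(0, keepdims=True)

    b = _mirror_x(_smooth_unit_field(rng, geometry.shape, sigma_vox))
    b = (b - b.min()) / max(b.max() - b.min(), 1e-12)
    baseline = 1.0 + 5.0 * b

    return GroundTruth(geometry, config, fractions, baseline, ki_true)


def _default_config(n_components: int) -> ModelConfig:
    from .occmodel import M2A

    if n_components == 2:
        return M2A
    # 4 components: drug A occupies three, drug B the shared high-affinity one
    return ModelConfig("M4", 4, {"A": (1, 2, 3), "B": (1,)})


def _default_ki(config: ModelConfig) -> Mapping[str, Mapping[int, float]]:
    out: dict[str, dict[int, float]] = {}
    for drug, comps in config.displaceable.items():
        base = 1.0 if drug == "A" else 1.5
        # successive components 12-fold apart in affinity
        out[drug] = {k: base * 12.0**rank for rank, k in enumerate(sorted(comps))}
    return out


def make_design(
    n_A: int = 8,
    n_B: int = 4,
    exposure_range: tuple[float, float] = (0.1, 120.0),
    seed: int = 0,
    jitter: float = 0.15,
) -> StudyDesign:
    """Two-arm single-dose design with log-spaced, jittered exposures.

    Exposures are log-spaced across ``exposure_range`` within each arm
    with multiplicative log-normal jitter, so the occupancy curves of
    all components are sampled from near-zero to near-saturation.
    """
    if n_A < 2 or n_B < 2:
        raise ValueError("each arm needs at least 2 subjects")
    low, high = exposure_range
    if low >= high:
        raise ValueError(f"exposure_range low ({low}) must be < high ({high})")
    rng = np.random.default_rng(seed)
    rows = []
    for drug, n in (("A", n_A), ("B", n_B)):
        menu = DOSE_MENU[drug]
        exposures = np.geomspace(low, high, n) * np.exp(rng.normal(0.0, jitter, n))
        for i, cp in enumerate(exposures):
            rows.append(
                {
                    "subject": f"S{drug}{i + 1:02d}",
                    "drug": drug,
                    "dose_mg": menu[i % len(menu)],
                    "exposure": float(cp),
                }
            )
    return StudyDesign(pd.DataFrame(rows))


def true_total_occupancy(truth: GroundTruth, drug: str, exposure: float) -> np.ndarray:
    """Noise-free per-voxel total occupancy for one occasion."""
    if drug not in truth.ki:
        raise ValueError(f"drug '{drug}' has no true K_i table")
    occ = np.zeros(truth.geometry.shape)
    for k in truth.config.displaceable[drug]:
        ki = truth.ki[drug][k]
        occ += truth.fractions[k - 1] * (exposure / (exposure + ki))
    return occ


def simulate_study(
    truth: GroundTruth,
    design: StudyDesign,
    noise_sd_occ: float = DEFAULT_NOISE_SD_OCC,
    baseline_cv: float = DEFAULT_BASELINE_CV,
    seed: int = 0,
) -> tuple[list[ElementMap], list[ElementMap]]:
    """Simulate per-occasion baseline and post-drug BP_ND maps.

    The total occupancy at a voxel is the mixture of single-site
    occupancy curves weighted by the true fractions; Gaussian noise of
    SD ``noise_sd_occ`` is added on the occupancy scale, and the
    post-drug map is ``baseline x (1 - occupancy)``.  Each subject's
    baseline is the truth baseline with independent per-element
    multiplicative log-normal variability of coefficient of variation
    ``baseline_cv``.
    """
    if noise_sd_occ < 0:
        raise ValueError("noise_sd_occ must be >= 0")
    for drug in design.drugs:
        if drug not in truth.ki:
            raise ValueError(f"drug '{drug}' absent from the truth K_i table")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(baseline_cv**2))
    baselines: list[ElementMap] = []
    posts: list[ElementMap] = []
    for row in design.table.itertuples(index=False):
        jit = (
            np.exp(rng.normal(-0.5 * sigma**2, sigma, truth.geometry.shape))
            if baseline_cv > 0
            else 1.0
        )
        bl = truth.baseline * jit
        occ = true_total_occupancy(truth, row.drug, row.exposure)
        if noise_sd_occ > 0:
            occ = occ + rng.normal(0.0, noise_sd_occ, truth.geometry.shape)
        baselines.append(ElementMap(truth.geometry, bl))
        posts.append(ElementMap(truth.geometry, bl * (1.0 - occ)))
    return baselines, posts


def region_mean_fractions(truth: GroundTruth) -> pd.DataFrame:
    """Region-mean true fractional contributions (hemispheres pooled)."""
    geo = truth.geometry
    rows = {}
    for rid in geo.region_ids:
        sel = (geo.regions == rid) & geo.mask
        rows[int(rid)] = truth.fractions[:, sel].mean(axis=1)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"C{k + 1}" for k in range(truth.n_components)]
    df.index.name = "region"
    return df


def make_gene_expression(
    truth: GroundTruth,
    geometry: Geometry,
    gene_names: Sequence[str] = DEFAULT_GENES,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Region x gene expression table tracking the true components.

    Gene ``gene_names[k]`` is linked 1:1 to component ``k+1`` for the
    first N genes: its regional expression is the region-mean true
    fractional contribution scaled by a common factor, under
    multiplicative log-normal noise (keeping values positive).  Extra
    genes beyond N are unlinked and get random positive levels.  With
    ``noise_sd = 0`` the fractional expression of a linked gene equals
    the region-mean fraction of its component exactly.
    """
    n = truth.n_components
    if len(gene_names) < n:
        raise ValueError(f"need at least {n} genes (one per component), got {len(gene_names)}")
    rng = np.random.default_rng(seed)
    means = region_mean_fractions(truth)
    n_regions = len(means)
    data = {}
    for k, gene in enumerate(gene_names):
        if k < n:
            base = truth.gene_scale * means.iloc[:, k].to_numpy()
        else:
            base = truth.gene_scale * rng.uniform(0.05, 0.30, n_regions)
        noise = np.exp(rng.normal(0.0, noise_sd, n_regions)) if noise_sd > 0 else 1.0
        data[gene] = base * noise
    table = pd.DataFrame(data, index=means.index)
    table.index.name = "region"
    return table
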