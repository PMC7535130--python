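"""Synthetic multispectral field scenes with exact ground truth.

Scenes emulate UAV plot imagery of rice canopies: the canopy is a union
of overlapping anisotropic Gaussian blobs with a high-frequency ripple
along the boundary (leaf texture), rendered into four reflectance bands
with class-dependent means.  Lowland plots sit on a dark, water-like
background; upland plots on a bright dry-soil background.  Optional
artifacts — a multiplicative shadow patch and a clipped overexposed
patch — reproduce the failure modes that defeat plain colour clustering.

A *trial* draws plot-level dry/fresh biomass for two genotypes under two
production systems across the three phenological stages (vegetative <
reproductive < ripening mean biomass), maps biomass to canopy NIR
through a saturating NDVI-style curve, and renders one scene per record,
so segmentation, feature extraction and the biomass estimators can all
be validated against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import BandRaster, MultispectralScene, stack_scene

GENOTYPES = ("IR64", "Line23")
SYSTEMS = ("lowland", "upland")
STAGES = ("vegetative", "reproductive", "ripening")

#: canopy band means (reflectance); NIR may be overridden per scene
CANOPY_MEANS = dict(nir=0.60, red=0.08, green=0.15, red_edge=0.40)
SOIL_MEANS = dict(
    lowland=dict(nir=0.05, red=0.06, green=0.07, red_edge=0.05),  # flooded paddy
    upland=dict(nir=0.30, red=0.35, green=0.30, red_edge=0.32),  # dry bright soil
)


@dataclass
class SceneSpec:
    shape: tuple[int, int] = (256, 256)
    canopy_fraction: float = 0.6
    stage: str = "vegetative"
    genotype: str = "IR64"
    system: str = "lowland"
    noise_sd: float = 0.02
    shadow: bool = False
    overexposure: bool = False
    seed: int = 0
    canopy_nir: float | None = None  # override tied to biomass in trials
    scene_id: str = ""

    def __post_init__(self) -> None:
        if not 0.05 < self.canopy_fraction < 0.95:
            raise ValueError("canopy_fraction must lie in (0.05, 0.95)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.system not in SYSTEMS:
            raise ValueError(f"unknown system {self.system!r}")


def _canopy_field(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Smooth blob field + ripple texture whose level sets look leaf-like."""
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    f = np.zeros((H, W))
    n_blobs = max(6, (H * W) // 2500)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, H), rng.uniform(0, W)
        theta = rng.uniform(0, np.pi)
        s1 = rng.uniform(0.08, 0.25) * min(H, W)
        s2 = rng.uniform(0.04, 0.12) * min(H, W)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        f += np.exp(-0.5 * ((u / s1) ** 2 + (v / s2) ** 2))
    # high-frequency ripple so the boundary grows leaf-scale lobes
    for _ in range(4):
        kx, ky = rng.uniform(0.2, 0.7, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        f += 0.06 * f.std() * np.sin(kx * xx + ky * yy + phase)
    return f


def generate_scene(spec: SceneSpec) -> MultispectralScene:
    """Render one plot scene; deterministic given ``spec.seed``.

    The canopy mask is the field's upper quantile, so the realized canopy
    fraction matches the target up to discretisation.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.shape
    f = _canopy_field(spec.shape, rng)
    thresh = np.quantile(f, 1.0 - spec.canopy_fraction)
    mask = (f > thresh).astype(np.uint8)

    canopy_means = dict(CANOPY_MEANS)
    if spec.canopy_nir is not None:
        canopy_means["nir"] = float(spec.canopy_nir)
    soil_means = SOIL_MEANS[spec.system]

    bands: dict[str, BandRaster] = {}
    band_values: dict[str, np.ndarray] = {}
    for name in ("green", "red", "red_edge", "nir"):
        vals = np.where(mask == 1, canopy_means[name], soil_means[name]).astype(np.float64)
        if spec.noise_sd > 0:
            vals = vals + rng.normal(0.0, spec.noise_sd, size=(H, W))
        band_values[name] = vals

    if spec.shadow:
        band_values = _apply_shadow(band_values, rng, spec.shape)
    if spec.overexposure:
        band_values = _apply_overexposure(band_values, rng, spec.shape)

    for name, vals in band_values.items():
        bands[name] = BandRaster(np.clip(vals, 0.0, 1.0), name)
    return stack_scene(bands, ground_truth_mask=mask, scene_id=spec.scene_id)


def _ellipse_mask(shape, rng, frac_lo=0.08, frac_hi=0.18) -> np.ndarray:
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    cy, cx = rng.uniform(0.2 * H, 0.8 * H), rng.uniform(0.2 * W, 0.8 * W)
    ry = rng.uniform(frac_lo, frac_hi) * H
    rx = rng.uniform(frac_lo, frac_hi) * W
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _apply_shadow(band_values, rng, shape):
    """Multiplicative dimming patch (cast shadow after sunshine-sensor
    compensation dims moderately rather than blacking out)."""
    patch = _ellipse_mask(shape, rng)
    dim = rng.uniform(0.55, 0.75)
    return {n: np.where(patch, v * dim, v) for n, v in band_values.items()}


def _apply_overexposure(band_values, rng, shape):
    """Small clipped-highlight patch: values pushed towards 1 but keeping
    texture, as in sun glint on wet soil or specular leaves."""
    patch = _ellipse_mask(shape, rng, 0.05, 0.12)
    opacity = rng.uniform(0.5, 0.75)
    return {n: np.where(patch, v + opacity * (1.0 - v), v) for n, v in band_values.items()}


# --------------------------------------------------------------------------
# trial generation


@dataclass
class TrialEffects:
    """Biomass / reflectance structure of a simulated trial.

    Stage mean dry biomass rises through the cycle (g per 4.95 m^2 plot);
    IR64 carries a positive biomass offset (largest under upland, where it
    out-accumulates Line23 despite its shorter stature).  Canopy NIR is
    tied to biomass through the saturating curve
    NDVI = a * BM / (b + BM) at fixed red reflectance, so NDVI loses
    sensitivity at high biomass exactly as dense real canopies do.
    """

    stage_dry_mean: dict = field(
        default_factory=lambda: dict(vegetative=200.0, reproductive=600.0, ripening=1000.0)
    )
    stage_dry_sd_frac: float = 0.15
    stage_water_content: dict = field(
        default_factory=lambda: dict(vegetative=0.85, reproductive=0.70, ripening=0.50)
    )
    water_content_sd: float = 0.03
    genotype_offset_frac: dict = field(
        default_factory=lambda: dict(lowland=0.10, upland=0.18)  # IR64 minus Line23
    )
    ndvi_a: float = 0.95
    ndvi_b: float = 250.0
    red_ref: float = 0.08
    stage_canopy_fraction: dict = field(
        default_factory=lambda: dict(vegetative=0.40, reproductive=0.60, ripening=0.75)
    )


def biomass_to_nir(dry_biomass: float, eff: TrialEffects) -> float:
    """Invert NDVI = a BM / (b + BM) for canopy NIR at fixed red."""
    ndvi = eff.ndvi_a * dry_biomass / (eff.ndvi_b + dry_biomass)
    ndvi = min(ndvi, 0.98)
    return float(np.clip(eff.red_ref * (1 + ndvi) / (1 - ndvi), 0.0, 0.98))


def generate_trial(
    n_per_stage: int = 50,
    seed: int = 0,
    shape: tuple[int, int] = (96, 96),
    effects: TrialEffects | None = None,
    noise_sd: float = 0.02,
    systems: tuple[str, ...] = SYSTEMS,
    artifacts: bool = False,
) -> tuple[list[MultispectralScene], pd.DataFrame]:
    """Simulate a ground-truthed trial: scenes plus the biomass table.

    Scenes cycle through genotype x system x spatial repetition within
    each stage.  Returns the scene list and a table with one record per
    scene (scene_id, rep, genotype, system, stage, dry/fresh biomass,
    water content).
    """
    if n_per_stage < 2:
        raise ValueError("need at least 2 scenes per stage")
    eff = effects or TrialEffects()
    if eff.stage_dry_sd_frac < 0 or not 0 < eff.ndvi_a <= 1 or eff.ndvi_b <= 0:
        raise ValueError("invalid effect parameters")
    rng = np.random.default_rng(seed)
    scenes: list[MultispectralScene] = []
    records = []
    idx = 0
    for stage in STAGES:
        mean_bm = eff.stage_dry_mean[stage]
        for i in range(n_per_stage):
            genotype = GENOTYPES[i % 2]
            system = systems[(i // 2) % len(systems)]
            rep = (i // (2 * len(systems))) % 3 + 1
            # the genotype offset is stature-mediated: IR64 packs more
            # biomass under a similar-looking canopy, so reflectance is
            # derived from the pre-offset biomass
            offset = eff.genotype_offset_frac[system] if genotype == "IR64" else 0.0
            base = max(rng.normal(mean_bm, eff.stage_dry_sd_frac * mean_bm), 0.05 * mean_bm)
            dry = base * (1 + offset)
            wc = float(
                np.clip(
                    rng.normal(eff.stage_water_content[stage], eff.water_content_sd),
                    0.05, 0.95,
                )
            )
            fresh = dry / (1.0 - wc)
            scene_id = f"{stage[:3]}-{idx:04d}"
            spec = SceneSpec(
                shape=shape,
                canopy_fraction=float(
                    np.clip(rng.normal(eff.stage_canopy_fraction[stage], 0.05), 0.15, 0.9)
                ),
                stage=stage,
                genotype=genotype,
                system=system,
                noise_sd=noise_sd,
                shadow=artifacts and bool(rng.random() < 0.5),
                overexposure=artifacts and bool(rng.random() < 0.5),
                seed=int(rng.integers(0, 2**31 - 1)),
                canopy_nir=biomass_to_nir(base, eff),
                scene_id=scene_id,
            )
            scenes.append(generate_scene(spec))
            records.append(
                dict(scene_id=scene_id, rep=rep, genotype=genotype, system=system,
                     stage=stage, dry_biomass=float(dry), fresh_biomass=float(fresh),
                     water_content=wc)
            )
            idx += 1
    return scenes, pd.DataFrame(records)


def stress_scene_specs(
    n_scenes: int = 50,
    seed: int = 0,
    shape: tuple[int, int] = (96, 96),
    noise_range: tuple[float, float] = (0.10, 0.20),
    canopy_range: tuple[float, float] = (0.3, 0.8),
) -> list[SceneSpec]:
    """Specs for the segmentation stress suite.

    Canopy fraction and per-band noise are swept uniformly; shadow and
    overexposure artifacts each appear with probability 0.7, and lowland
    and upland backgrounds alternate.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_scenes):
        specs.append(
            SceneSpec(
                shape=shape,
                canopy_fraction=float(rng.uniform(*canopy_range)),
                noise_sd=float(rng.uniform(*noise_range)),
                shadow=bool(rng.random() < 0.7),
                overexposure=bool(rng.random() < 0.7),
                system=SYSTEMS[i % 2],
                seed=int(rng.integers(0, 2**31 - 1)),
                scene_id=f"stress-{i:03d}",
            )
        )
    return specs
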