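"""Synthetic assay data with known ground truth.

Every wet-lab readout of the reporter system has a generator here: gel lane
profiles and two-channel gel images (NanoLuc sample lanes plus a DiI-LDL
standard lane), plate-reader developmental time courses with a reporter
allele-dosage effect, 10-fraction density-gradient runs, EM particle
diameter populations, and two-exposure whole-larva chemiluminescence image
stacks with region masks.  Each generator is a pure function of its
parameters and seed, and writes a :class:`GroundTruth` record that fully
determines the expected analysis output — the basis of the closed-loop
tests in which noiseless generation followed by analysis must recover the
truth.

Modelling choices (see docs/methods.md): bands are Gaussian in ladder-unit
space; plate noise is lognormal (multiplicative, CV-parameterized); camera
noise is additive Gaussian with no blank subtraction; the long/short
exposure ratio is fixed at 3.0 (30 s / 10 s) before clipping.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .electrophoresis import LaneProfile
from .gradient import GradientRun, ParticlePopulation, density_to_ri
from .microscopy import LarvaImageStack, REGION_LABELS, REGIONS
from .presets import SUBCLASSES, GenotypePreset

EXPOSURE_RATIO = 3.0  # 30 s / 10 s, before clipping


@dataclass
class GroundTruth:
    """Truth sidecar written alongside every synthetic artifact."""

    kind: str
    seed: int | None
    data: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Gel lanes and gel images
# ---------------------------------------------------------------------------

LDL_UPPER_LU = 2.4  # nominal end of the classified mobility range
DEFAULT_LANE_SIGNAL = 1e4  # total intensity per lane (arbitrary DN)
STANDARD_SIGMA_LU = 0.03  # width of the DiI standard band


def make_lane_profile(
    preset: GenotypePreset,
    axis_len_px: int,
    standard_px: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
    total_signal: float = DEFAULT_LANE_SIGNAL,
) -> tuple[LaneProfile, GroundTruth]:
    """One sample-lane intensity profile: Gaussian bands in LU space.

    ``standard_px`` defines 1 LU.  The axis must reach past the LDL bin
    (>= 2.4 x standard_px rows) so no class is truncated.  Additive
    Gaussian noise (sd in intensity units) is clipped at 0.
    """
    if standard_px <= 0:
        raise ValueError("standard_px must be positive")
    if axis_len_px < LDL_UPPER_LU * standard_px:
        raise ValueError(
            f"axis too short for LDL bin: need >= {LDL_UPPER_LU} x standard_px "
            f"= {LDL_UPPER_LU * standard_px:.0f} rows, got {axis_len_px}"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rows = np.arange(axis_len_px, dtype=float)
    profile = np.zeros(axis_len_px)
    for band in preset.bands:
        mu = band.center_lu * standard_px
        sigma = band.sigma_lu * standard_px
        profile += band.weight * total_signal * sps.norm.pdf(rows, mu, sigma)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        profile = np.clip(profile + rng.normal(0.0, noise_sd, axis_len_px), 0.0, None)
    truth = GroundTruth(
        "lane_profile",
        seed,
        {
            "preset": preset.name,
            "class_weights": dict(preset.class_weights),
            "standard_px": standard_px,
            "total_signal": total_signal,
            "noise_sd": noise_sd,
        },
    )
    return LaneProfile(profile, lane_id=preset.name), truth


def make_standard_profile(
    axis_len_px: int,
    standard_px: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
    total_signal: float = DEFAULT_LANE_SIGNAL,
) -> LaneProfile:
    """The DiI-LDL standard lane: a single band at 1 LU."""
    rows = np.arange(axis_len_px, dtype=float)
    profile = total_signal * sps.norm.pdf(rows, standard_px, STANDARD_SIGMA_LU * standard_px)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        profile = np.clip(profile + rng.normal(0.0, noise_sd, axis_len_px), 0.0, None)
    return LaneProfile(profile, lane_id="standard")


@dataclass(frozen=True)
class GelGeometry:
    """Raster layout of a synthetic gel image."""

    axis_len_px: int = 260
    standard_px: float = 100.0
    lane_width_px: int = 20
    gap_px: int = 6
    origin_px: int = 8  # loading-well row within the image
    bit_depth: int = 16
    peak_dn: float = 20000.0  # target peak per-pixel intensity

    @property
    def ceiling(self) -> int:
        return 2**self.bit_depth - 1


@dataclass
class GelImage:
    """Two-channel synthetic gel: NanoLuc samples + DiI standard."""

    lipo_channel: np.ndarray  # chemiluminescent exposure (sample lanes)
    dii_channel: np.ndarray  # fluorescent exposure (standard lane only)
    lane_bounds: dict[str, tuple[int, int]]
    origin_px: int
    standard_lane: str | None
    geometry: GelGeometry


def make_gel_image(
    lane_presets: list[GenotypePreset],
    standard_lane: bool = True,
    geometry: GelGeometry | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[GelImage, GroundTruth]:
    """Render a two-channel 16-bit gel image.

    Lane 1 is the DiI standard (when ``standard_lane``), mirroring the
    usual gel layout; sample lanes follow in order.  The DiI channel holds
    only the standard band, the NanoLuc channel only the sample lanes.  A
    saturation warning is recorded in the truth sidecar if more than 1% of
    in-lane pixels clip.
    """
    if not lane_presets:
        raise ValueError("need at least one sample lane")
    geom = geometry or GelGeometry()
    n_lanes = len(lane_presets) + (1 if standard_lane else 0)
    width = n_lanes * (geom.lane_width_px + geom.gap_px) + geom.gap_px
    height = geom.origin_px + geom.axis_len_px
    lipo = np.zeros((height, width))
    dii = np.zeros((height, width))
    rng = np.random.default_rng(seed)
    ss = rng.spawn(n_lanes + 2)

    bounds: dict[str, tuple[int, int]] = {}
    lane_order: list[str] = []

    def lane_cols(i: int) -> tuple[int, int]:
        lo = geom.gap_px + i * (geom.lane_width_px + geom.gap_px)
        return lo, lo + geom.lane_width_px

    lane_i = 0
    if standard_lane:
        lo, hi = lane_cols(lane_i)
        prof = make_standard_profile(geom.axis_len_px, geom.standard_px)
        dii[geom.origin_px:, lo:hi] = prof.intensities[:, None] / geom.lane_width_px
        bounds["standard"] = (lo, hi)
        lane_order.append("standard")
        lane_i += 1
    truth_lanes = {}
    for p_i, preset in enumerate(lane_presets):
        lo, hi = lane_cols(lane_i)
        lane_id = f"lane{lane_i + 1}_{preset.name}"
        prof, _ = make_lane_profile(
            preset, geom.axis_len_px, geom.standard_px,
            seed=int(ss[p_i].integers(2**31)),
        )
        lipo[geom.origin_px:, lo:hi] = prof.intensities[:, None] / geom.lane_width_px
        bounds[lane_id] = (lo, hi)
        lane_order.append(lane_id)
        truth_lanes[lane_id] = dict(preset.class_weights)
        lane_i += 1

    # Scale to the target peak intensity, add camera noise, quantize.
    scale = geom.peak_dn / max(lipo.max(), dii.max(), 1e-12)
    lipo *= scale
    dii *= scale
    if noise_sd > 0:
        lipo = lipo + ss[-2].normal(0.0, noise_sd, lipo.shape)
        dii = dii + ss[-1].normal(0.0, noise_sd, dii.shape)
    lipo16 = np.clip(np.rint(lipo), 0, geom.ceiling).astype(np.uint16)
    dii16 = np.clip(np.rint(dii), 0, geom.ceiling).astype(np.uint16)

    in_lane = np.zeros(lipo16.shape, dtype=bool)
    for lo, hi in bounds.values():
        in_lane[:, lo:hi] = True
    n_sat = int(((lipo16 == geom.ceiling) | (dii16 == geom.ceiling))[in_lane].sum())
    saturation_warning = n_sat > 0.01 * in_lane.sum()

    truth = GroundTruth(
        "gel_image",
        seed,
        {
            "n_lanes": n_lanes,
            "lane_order": lane_order,
            "lane_bounds": {k: list(v) for k, v in bounds.items()},
            "standard_px": geom.standard_px,
            "origin_px": geom.origin_px,
            "class_weights": truth_lanes,
            "saturation_warning": saturation_warning,
            "noise_sd": noise_sd,
        },
    )
    gel = GelImage(lipo16, dii16, bounds, geom.origin_px,
                   "standard" if standard_lane else None, geom)
    return gel, truth


# ---------------------------------------------------------------------------
# Plate-reader time courses
# ---------------------------------------------------------------------------

# Canonical wild-type developmental profile (1-6 dpf): reporter signal rises
# while yolk lipid is packaged into particles, peaks at 3 dpf, then declines
# as turnover outpaces production after yolk depletion.
WT_STAGE_PROFILE = {1: 0.20, 2: 0.60, 3: 1.00, 4: 0.85, 5: 0.65, 6: 0.45}


def make_plate_timecourse(
    genotype_alleles: dict[str, int],
    timepoints=tuple(range(1, 7)),
    n_per_cell: int = 24,
    per_allele_signal: float = 1000.0,
    cv: float = 0.2,
    stage_profile: dict | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-well relative luminescence for a genotype x timepoint design.

    Expected signal per well is (allele count) x ``per_allele_signal`` x
    stage multiplier, so homozygotes (2 tagged alleles) average twice their
    heterozygous siblings.  Well-to-well noise is lognormal with the stated
    CV (multiplicative pipetting/homogenization error); cv = 0 gives the
    exact expectation.
    """
    if per_allele_signal < 0 or cv < 0:
        raise ValueError("signal parameters must be non-negative")
    if n_per_cell < 2:
        raise ValueError("need n >= 2 wells per cell")
    if any(a < 0 for a in genotype_alleles.values()):
        raise ValueError("allele counts must be non-negative")
    timepoints = list(timepoints)
    if stage_profile is None:
        stage_profile = (
            dict(WT_STAGE_PROFILE)
            if all(t in WT_STAGE_PROFILE for t in timepoints)
            else {t: 1.0 for t in timepoints}
        )
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))
    rows = []
    expected = {}
    well = 0
    for group, alleles in genotype_alleles.items():
        for t in timepoints:
            mean = alleles * per_allele_signal * stage_profile[t]
            expected[(group, t)] = mean
            if cv > 0 and mean > 0:
                vals = mean * np.exp(rng.normal(-sigma**2 / 2, sigma, n_per_cell))
            else:
                vals = np.full(n_per_cell, mean)
            for v in vals:
                rows.append(
                    {
                        "well_id": f"W{well:04d}",
                        "sample_id": f"{group}_t{t}_{well:04d}",
                        "group": group,
                        "timepoint": t,
                        "rlu": float(v),
                    }
                )
                well += 1
    reads = pd.DataFrame(rows)
    truth = GroundTruth(
        "plate_timecourse",
        seed,
        {
            "genotype_alleles": dict(genotype_alleles),
            "per_allele_signal": per_allele_signal,
            "cv": cv,
            "stage_profile": {str(k): v for k, v in stage_profile.items()},
            "expected_means": {f"{g}@{t}": m for (g, t), m in expected.items()},
        },
    )
    return reads, truth


# ---------------------------------------------------------------------------
# Density-gradient runs
# ---------------------------------------------------------------------------


def make_gradient_run(
    preset: GenotypePreset,
    n_fractions: int = 10,
    density_range: tuple[float, float] = (1.11, 1.03),
    signal_total: float = 1e4,
    noise_cv: float = 0.0,
    seed: int | None = None,
    run_id: str | None = None,
) -> tuple[GradientRun, GroundTruth]:
    """One drip-eluted gradient run (fraction 1 = densest, eluted first).

    Densities descend linearly from ``density_range[0]`` (bottom) to
    ``density_range[1]`` (top); refractive indices are generated by
    inverting the linear RI->density calibration, so the analysis round
    trip reproduces the ladder exactly.  Reporter signal is a Gaussian bump
    over fraction index centred on the preset's peak fraction (buoyant
    VLDL-rich genotypes peak late, dense LDL-shifted genotypes early).
    """
    if n_fractions < 2:
        raise ValueError("need at least 2 fractions")
    bottom, top = density_range
    if bottom <= top:
        raise ValueError("bottom density must exceed top density (fraction 1 elutes first)")
    idx = np.arange(1, n_fractions + 1)
    densities = np.linspace(bottom, top, n_fractions)
    ri = density_to_ri(densities)
    signal = np.exp(-0.5 * ((idx - preset.gradient_peak_fraction) / preset.gradient_peak_width) ** 2)
    signal = signal / signal.sum() * signal_total
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        signal = signal * np.exp(rng.normal(-sigma**2 / 2, sigma, n_fractions))
    run = GradientRun(idx, ri, signal, run_id=run_id or f"{preset.name}_run")
    truth = GroundTruth(
        "gradient_run",
        seed,
        {
            "preset": preset.name,
            "densities": densities,
            "peak_fraction": preset.gradient_peak_fraction,
            "density_range": list(density_range),
            "noise_cv": noise_cv,
        },
    )
    return run, truth


# ---------------------------------------------------------------------------
# EM particle populations
# ---------------------------------------------------------------------------


def make_particle_sample(
    mean_nm: float,
    sd_nm: float,
    n: int,
    seed: int | None = None,
    fraction_label: str = "",
    genotype: str = "",
) -> ParticlePopulation:
    """Particle diameters from a Normal truncated at 0 (diameters > 0)."""
    if mean_nm <= 0:
        raise ValueError("mean diameter must be positive")
    if sd_nm < 0:
        raise ValueError("sd must be non-negative")
    if n < 1:
        raise ValueError("need n >= 1 particles")
    if sd_nm == 0:
        d = np.full(n, mean_nm)
    else:
        rng = np.random.default_rng(seed)
        a = (0.0 - mean_nm) / sd_nm
        d = sps.truncnorm.rvs(a, np.inf, loc=mean_nm, scale=sd_nm, size=n, random_state=rng)
    return ParticlePopulation(d, fraction_label=fraction_label, genotype=genotype)


# ---------------------------------------------------------------------------
# Larva image stacks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LarvaGeometry:
    """Raster layout of the synthetic larva silhouette."""

    shape: tuple[int, int] = (120, 260)
    bit_depth: int = 16

    @property
    def ceiling(self) -> int:
        return 2**self.bit_depth - 1


def make_larva_masks(geometry: LarvaGeometry | None = None) -> np.ndarray:
    """Label image partitioning a stylized larva into viscera/trunk/head.

    Labels: 0 background, 1 viscera (ventral ellipse), 2 trunk (posterior
    band), 3 head (anterior disc).  Regions are pairwise disjoint by
    construction and jointly form the larva silhouette.
    """
    geom = geometry or LarvaGeometry()
    h, w = geom.shape
    rr, cc = np.mgrid[0:h, 0:w]
    head = (rr - 55) ** 2 + (cc - 40) ** 2 <= 25**2
    viscera = ((rr - 72) / 26.0) ** 2 + ((cc - 105) / 45.0) ** 2 <= 1.0
    trunk = (rr >= 42) & (rr <= 66) & (cc >= 150) & (cc <= 248)
    viscera &= ~head
    trunk &= ~(head | viscera)
    masks = np.zeros(geom.shape, dtype=np.uint8)
    masks[viscera] = REGION_LABELS["viscera"]
    masks[trunk] = REGION_LABELS["trunk"]
    masks[head] = REGION_LABELS["head"]
    return masks


def make_larva_image(
    region_fractions: dict[str, float],
    total_signal: float = 1e6,
    geometry: LarvaGeometry | None = None,
    noise_sd: float = 0.0,
    saturate_long: bool = False,
    seed: int | None = None,
    masks: np.ndarray | None = None,
) -> tuple[LarvaImageStack, np.ndarray, GroundTruth]:
    """Two-exposure chemiluminescent stack of one larva plus region masks.

    The short (10 s) frame distributes ``total_signal`` across the three
    regions in the requested proportions (uniform within each region); the
    long (30 s) frame is exactly 3x the short frame before clipping at the
    bit ceiling.  With ``saturate_long`` the image is rescaled so the long
    frame clips while the short frame stays in range — the condition the
    exposure-selection rule exists for.  Additive Gaussian camera noise is
    applied per frame and clipped to the valid range.
    """
    geom = geometry or LarvaGeometry()
    if set(region_fractions) != set(REGIONS):
        raise ValueError(f"region_fractions must have keys {REGIONS}")
    total_frac = sum(region_fractions.values())
    if abs(total_frac - 1.0) > 1e-9 or any(v < 0 for v in region_fractions.values()):
        raise ValueError("region fractions must be non-negative and sum to 1")
    if masks is None:
        masks = make_larva_masks(geom)
    else:
        masks = np.asarray(masks)
        if masks.shape != geom.shape:
            raise ValueError("mask shape must match geometry")
        if not set(np.unique(masks).tolist()) <= {0, 1, 2, 3}:
            raise ValueError("mask labels must be subset of {0,1,2,3}")
        if any((masks == lab).sum() == 0 for lab in (1, 2, 3)):
            raise ValueError("each region mask must be non-empty")

    short = np.zeros(geom.shape)
    for region, lab in REGION_LABELS.items():
        area = int((masks == lab).sum())
        short[masks == lab] = region_fractions[region] * total_signal / area

    # Rescale so the saturation state of the long frame matches the flag;
    # a global scale preserves the region fractions exactly.
    peak = short.max()
    if saturate_long:
        if EXPOSURE_RATIO * peak < geom.ceiling:
            short *= 1.05 * geom.ceiling / (EXPOSURE_RATIO * peak)
        if short.max() >= geom.ceiling:  # keep the short frame usable
            short *= 0.9 * geom.ceiling / short.max()
    elif EXPOSURE_RATIO * peak >= geom.ceiling:
        short *= 0.9 * geom.ceiling / (EXPOSURE_RATIO * peak)

    long = EXPOSURE_RATIO * short
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        short = short + rng.normal(0.0, noise_sd, geom.shape)
        long = long + rng.normal(0.0, noise_sd, geom.shape)
    # Frames stay float (clipped to the sensor range) so the noiseless
    # closed loop is exact; quantization to uint16 happens on TIFF export.
    short = np.clip(short, 0, geom.ceiling)
    long = np.clip(long, 0, geom.ceiling)

    stack = LarvaImageStack(short, long, bit_ceiling=geom.ceiling)
    truth = GroundTruth(
        "larva_image",
        seed,
        {
            "region_fractions": dict(region_fractions),
            "saturate_long": saturate_long,
            "noise_sd": noise_sd,
            "expected_exposure": "short" if saturate_long else "long",
        },
    )
    return stack, masks, truth
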