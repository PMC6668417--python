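"""Native-PAGE densitometry: ladder-unit registration and subclass binning.

A gel lane is reduced to a 1-D intensity profile along the migration axis.
The DiI-labelled human LDL standard run on every gel defines the ladder
unit (LU): the distance from the loading well to the standard's band peak
is 1 LU, which registers lanes onto a common axis regardless of run time or
gel batch.  Signal is then binned into the four mobility classes —
ZM (zero mobility, < 0.3 LU), VLDL (0.3–1 LU), IDL (1–1.7 LU) and
LDL (1.7–2.4 LU) — and reported as relative abundance (percent of lane
signal), never absolute abundance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

log = logging.getLogger(__name__)

SUBCLASSES = ("ZM", "VLDL", "IDL", "LDL")


@dataclass
class LaneProfile:
    """1-D intensity profile along the migration axis of one lane.

    ``intensities[i]`` is the summed lane intensity ``i`` rows below the
    loading well (the origin, 0 LU).  Migration increases downward.
    """

    intensities: np.ndarray
    origin_px: int = 0
    px_per_row: float = 1.0
    lane_id: str = "lane"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1:
            raise ValueError("intensities must be 1-D")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if self.px_per_row <= 0:
            raise ValueError("px_per_row must be positive")

    def migration_px(self) -> np.ndarray:
        """Migration distance (px) of each profile row from the origin."""
        return np.arange(self.intensities.size) * self.px_per_row


@dataclass(frozen=True)
class MigrationStandard:
    """Migration distance (px) of the DiI-LDL standard band; defines 1 LU."""

    migration_px: float

    def __post_init__(self) -> None:
        if self.migration_px <= 0:
            raise ValueError("standard migration must be positive")


@dataclass(frozen=True)
class BinScheme:
    """Ordered subclass boundaries in ladder units.

    ``edges_lu`` are the upper edges of (ZM, VLDL, IDL, LDL); the ZM lower
    edge is 0.  Bins are half-open ``[lower, upper)``; signal migrating past
    the nominal LDL edge is still counted as LDL so lane totals always reach
    100%.
    """

    edges_lu: tuple[float, float, float, float] = (0.3, 1.0, 1.7, 2.4)
    labels: tuple[str, str, str, str] = SUBCLASSES

    def __post_init__(self) -> None:
        e = self.edges_lu
        if len(e) != 4 or len(self.labels) != 4:
            raise ValueError("need exactly 4 edges and 4 labels")
        if not (0 < e[0] < e[1] < e[2] < e[3]):
            raise ValueError("edges must be strictly increasing and positive")


def default_bin_scheme() -> BinScheme:
    """The standard classification rule: edges 0.3 / 1.0 / 1.7 / 2.4 LU."""
    return BinScheme()


def extract_lane_profile(
    gel_image: np.ndarray,
    lane_bounds: tuple[int, int],
    origin_px: int = 0,
    lane_id: str = "lane",
) -> LaneProfile:
    """Row-wise sum of intensities across the lane's columns, origin downward.

    ``lane_bounds`` is a half-open column interval ``(lo, hi)``.
    """
    img = np.asarray(gel_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("gel image must be 2-D")
    lo, hi = lane_bounds
    if not (0 <= lo < hi <= img.shape[1]):
        raise ValueError(f"lane bounds {lane_bounds} outside image width {img.shape[1]}")
    if not (0 <= origin_px < img.shape[0]):
        raise ValueError("origin row outside image")
    profile = img[origin_px:, lo:hi].sum(axis=1)
    return LaneProfile(profile, origin_px=origin_px, lane_id=lane_id)


def locate_standard(profile: LaneProfile, smooth_window: int = 5) -> MigrationStandard:
    """Find the DiI standard band: peak of the moving-average-smoothed profile.

    Ties break toward the smaller migration distance.  A flat profile
    (max == min) means no band and is rejected.
    """
    y = profile.intensities
    if y.size == 0 or np.max(y) == np.min(y):
        raise ValueError("no standard detected: profile is flat")
    if smooth_window > 1:
        y = uniform_filter1d(y, size=smooth_window, mode="nearest")
    # A narrow band becomes a flat-topped plateau after smoothing: take the
    # center of the first maximal plateau, so ties break toward the smaller
    # migration and a symmetric band keeps its true peak row.
    at_max = np.flatnonzero(y == y.max())
    first_run_end = np.argmax(np.diff(at_max, prepend=at_max[0] - 1) != 1) or at_max.size
    peak_row = int(round(at_max[:first_run_end].mean()))
    migration = peak_row * profile.px_per_row
    if migration <= 0:
        raise ValueError("standard band found at the origin; not a valid migration")
    return MigrationStandard(migration_px=migration)


def bin_cutoffs_px(scheme: BinScheme, standard: MigrationStandard) -> np.ndarray:
    """Bin upper edges in pixels: each LU edge times the standard migration.

    The returned values are the upper boundaries of (ZM, VLDL, IDL, LDL);
    in use the final LDL bin extends to the end of the profile.
    """
    return np.asarray(scheme.edges_lu, dtype=float) * standard.migration_px


@dataclass
class SubclassAbundance:
    """Relative abundance (% of lane signal) per mobility subclass."""

    percent: dict[str, float]
    lane_id: str = "lane"
    gel_id: str = "gel"

    def __post_init__(self) -> None:
        total = sum(self.percent.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"abundances must sum to 100% (got {total})")
        if any(not (0 <= v <= 100) for v in self.percent.values()):
            raise ValueError("each abundance must lie in [0, 100]")


def quantify_subclasses(
    profile: LaneProfile,
    standard: MigrationStandard,
    scheme: BinScheme | None = None,
    gel_id: str = "gel",
) -> SubclassAbundance:
    """Bin a lane profile into subclass relative abundances.

    Rows are mapped to LU by dividing migration distance by the standard
    migration; intensity is summed within each half-open bin and normalized
    to 100%.  Signal beyond the LDL upper edge counts as LDL.
    """
    scheme = scheme or default_bin_scheme()
    y = profile.intensities
    total = float(y.sum())
    if total <= 0:
        raise ValueError(f"empty lane: no signal in {profile.lane_id}")
    lu = profile.migration_px() / standard.migration_px
    # Interior edges only: everything >= IDL upper edge belongs to LDL.
    idx = np.digitize(lu, scheme.edges_lu[:3], right=False)
    percent = {
        label: float(y[idx == i].sum()) * 100.0 / total
        for i, label in enumerate(scheme.labels)
    }
    return SubclassAbundance(percent, lane_id=profile.lane_id, gel_id=gel_id)


@dataclass
class GelResult:
    """One analyzed gel: its detected standard and per-lane abundances."""

    gel_id: str
    standard: MigrationStandard | None
    abundances: list[SubclassAbundance]
    lane_meta: dict[str, dict] = field(default_factory=dict)


def analyze_gel_profiles(
    sample_profiles: list[LaneProfile],
    standard_profile: LaneProfile,
    scheme: BinScheme | None = None,
    gel_id: str = "gel",
    smooth_window: int = 5,
) -> GelResult:
    """Register one gel's lanes to its DiI standard and quantify each lane."""
    standard = locate_standard(standard_profile, smooth_window=smooth_window)
    abundances = [
        quantify_subclasses(p, standard, scheme=scheme, gel_id=gel_id)
        for p in sample_profiles
    ]
    return GelResult(gel_id=gel_id, standard=standard, abundances=abundances)


def register_gels(gels: list[GelResult]) -> pd.DataFrame:
    """Combine analyzed gels into one long-format cross-gel abundance table.

    All lanes are already on the common LU axis (each gel was registered to
    its own standard), so abundances are directly comparable.  Gels without
    a detected standard are excluded with a logged warning.  Returns columns
    (gel, lane, subclass, percent).
    """
    if not gels:
        raise ValueError("no gels to register")
    rows = []
    for gel in gels:
        if gel.standard is None:
            log.warning("gel %s has no detected standard; excluded", gel.gel_id)
            warnings.warn(f"gel {gel.gel_id} has no detected standard; excluded")
            continue
        for ab in gel.abundances:
            meta = gel.lane_meta.get(ab.lane_id, {})
            for subclass, pct in ab.percent.items():
                rows.append(
                    {"gel": gel.gel_id, "lane": ab.lane_id, "subclass": subclass,
                     "percent": pct, **meta}
                )
    if not rows:
        raise ValueError("no gels with a detected standard")
    return pd.DataFrame(rows)
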