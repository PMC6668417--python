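"""Density-gradient ultracentrifugation (DGUC) fraction analysis.

Lipoproteins separated on an iodixanol gradient are drip-eluted densest
first into (by default) 10 fractions.  The iodixanol concentration of each
fraction is read out optically as a refractive index and converted to
solution density with a linear calibration; reporter signal per fraction
then gives a density profile of the ApoB particle population.  Second-order
polynomial fits relate Native-PAGE electrophoretic mobility (in ladder
units) to fraction density and to EM particle diameter, which is what makes
gel mobility usable as a proxy for particle size and density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Linear refractive-index -> density calibration for iodixanol gradients
# (density in g/mL): D = 3.3508 * RI - 3.4675.
DENSITY_SLOPE = 3.3508
DENSITY_INTERCEPT = -3.4675


def ri_to_density(ri):
    """Convert refractive index to solution density (g/mL).

    Applies ``D = 3.3508 * RI - 3.4675``.  Accepts scalars or arrays.
    RI must exceed 1 (pure-water lower bound for aqueous media).
    """
    arr = np.asarray(ri, dtype=float)
    if np.any(arr <= 1.0):
        raise ValueError("refractive index must be > 1 for aqueous media")
    out = DENSITY_SLOPE * arr + DENSITY_INTERCEPT
    return float(out) if np.isscalar(ri) else out


def density_to_ri(density):
    """Inverse of :func:`ri_to_density`; used by the synthetic generator."""
    arr = np.asarray(density, dtype=float)
    out = (arr - DENSITY_INTERCEPT) / DENSITY_SLOPE
    return float(out) if np.isscalar(density) else out


@dataclass
class GradientRun:
    """One DGUC run: ordered fractions (1 = densest, first eluted)."""

    fraction_index: np.ndarray  # 1..n
    refractive_index: np.ndarray
    signal: np.ndarray  # relative luminescence per fraction
    run_id: str = "run"

    def __post_init__(self) -> None:
        self.fraction_index = np.asarray(self.fraction_index, dtype=int)
        self.refractive_index = np.asarray(self.refractive_index, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        n = len(self.fraction_index)
        if not (len(self.refractive_index) == len(self.signal) == n):
            raise ValueError("fraction_index, refractive_index, signal must align")
        if n < 2:
            raise ValueError("a gradient run needs at least 2 fractions")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, run_id: str = "run") -> "GradientRun":
        """Build from a table with columns fraction_index, refractive_index, signal."""
        df = df.sort_values("fraction_index")
        return cls(
            df["fraction_index"].to_numpy(),
            df["refractive_index"].to_numpy(),
            df["signal"].to_numpy(),
            run_id=run_id,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction_index": self.fraction_index,
                "refractive_index": self.refractive_index,
                "signal": self.signal,
            }
        )


def density_profile(run: GradientRun) -> pd.DataFrame:
    """Per-fraction densities plus a monotonicity report.

    Fraction 1 elutes from the dense bottom of the tube, so densities are
    expected to decrease with fraction index.  Any increase relative to the
    previous fraction is flagged (``inverted`` column) but not treated as an
    error — inversions indicate a disturbed gradient, not bad input.
    """
    dens = ri_to_density(run.refractive_index)
    inverted = np.zeros(len(dens), dtype=bool)
    inverted[1:] = np.diff(dens) > 0
    return pd.DataFrame(
        {
            "fraction_index": run.fraction_index,
            "density_g_ml": dens,
            "signal": run.signal,
            "inverted": inverted,
        }
    )


@dataclass(frozen=True)
class CalibrationCurve:
    """Second-order polynomial calibration ``y = a2*x**2 + a1*x + a0``."""

    a2: float
    a1: float
    a0: float
    r_squared: float
    x_role: str = "mobility_lu"
    y_role: str = "y"

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.a2, self.a1, self.a0)

    def __call__(self, x):
        return eval_poly2(self, x)

    def summary(self) -> str:
        return (
            f"y = {self.a2:.6g}*x^2 + {self.a1:+.6g}*x + {self.a0:+.6g}"
            f"   (x: {self.x_role}, y: {self.y_role}, R^2 = {self.r_squared:.5f})"
        )

    def to_dict(self) -> dict:
        return {
            "a2": self.a2,
            "a1": self.a1,
            "a0": self.a0,
            "r_squared": self.r_squared,
            "x_role": self.x_role,
            "y_role": self.y_role,
        }


# Published reference calibrations for wild-type larval zebrafish
# lipoproteins.  The first maps gel mobility (LU) to fraction density
# (g/mL, fractions 4-9); the second maps mobility to EM particle diameter
# (nm).  The diameter curve was originally captioned as a density relation,
# but its values (~36 at x = 1 LU) are on the nm scale; we label the roles
# explicitly rather than guessing (see docs/methods.md).
MOBILITY_DENSITY_REFERENCE = CalibrationCurve(
    0.0796, -0.1886, 1.136, r_squared=0.97737, x_role="mobility_lu", y_role="density_g_ml"
)
MOBILITY_DIAMETER_REFERENCE = CalibrationCurve(
    10.82, -44.551, 70.125, r_squared=0.79978, x_role="mobility_lu", y_role="diameter_nm"
)


def fit_poly2(x, y, x_role: str = "x", y_role: str = "y") -> CalibrationCurve:
    """Least-squares degree-2 fit with R² = 1 − SS_res/SS_tot.

    Needs at least 3 distinct x values.  A zero-variance y is treated as a
    perfect constant fit (R² = 1 by convention, avoiding 0/0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct x values for a degree-2 fit")
    a2, a1, a0 = np.polyfit(x, y, 2)
    resid = y - (a2 * x**2 + a1 * x + a0)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return CalibrationCurve(float(a2), float(a1), float(a0), r2, x_role=x_role, y_role=y_role)


def eval_poly2(curve: CalibrationCurve, x):
    x = np.asarray(x, dtype=float)
    out = curve.a2 * x**2 + curve.a1 * x + curve.a0
    return float(out) if out.ndim == 0 else out


@dataclass
class ParticlePopulation:
    """EM particle diameters (nm) from one gradient fraction."""

    diameters_nm: np.ndarray
    fraction_label: str = ""
    genotype: str = ""

    def __post_init__(self) -> None:
        self.diameters_nm = np.asarray(self.diameters_nm, dtype=float)
        if self.diameters_nm.size and np.any(self.diameters_nm <= 0):
            raise ValueError("particle diameters must be positive")


def summarize_diameters(pop: ParticlePopulation) -> dict[str, float]:
    """Mean, sample SD (n−1 denominator; 0 when n = 1), and n."""
    d = pop.diameters_nm
    n = int(d.size)
    if n == 0:
        raise ValueError("empty particle population")
    sd = float(np.std(d, ddof=1)) if n > 1 else 0.0
    return {"mean_nm": float(np.mean(d)), "sd_nm": sd, "n": n}
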