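"""Genotype presets for the synthetic assay generators.

Presets encode, qualitatively, the lipoprotein phenotype of each zebrafish
genotype used to validate the reporter system: subclass band composition on a
Native-PAGE gel (in ladder units), whole-larva regional signal fractions, and
the density-gradient fraction where reporter signal peaks.  The numbers are
declared fixtures shipped in ``presets.yaml`` — the published work reports
profile *shapes*, not numeric weights — and every field can be overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import yaml

SUBCLASSES = ("ZM", "VLDL", "IDL", "LDL")
REGIONS = ("viscera", "trunk", "head")

_TOL = 1e-9


@dataclass(frozen=True)
class Band:
    """One Gaussian band component in ladder-unit space."""

    subclass: str
    center_lu: float
    sigma_lu: float
    weight: float


@dataclass(frozen=True)
class GenotypePreset:
    """Synthetic phenotype of one genotype.

    Invariants (checked on construction): class weights and region fractions
    are non-negative and each sum to 1; band weights sum per subclass to the
    class weights.
    """

    name: str
    class_weights: dict[str, float]
    bands: tuple[Band, ...]
    region_fractions: dict[str, float]
    gradient_peak_fraction: float = 6.0
    gradient_peak_width: float = 1.5

    def __post_init__(self) -> None:
        for mapping, keys, what in (
            (self.class_weights, SUBCLASSES, "class_weights"),
            (self.region_fractions, REGIONS, "region_fractions"),
        ):
            if set(mapping) != set(keys):
                raise ValueError(f"{what} must have keys {keys}, got {sorted(mapping)}")
            if any(v < 0 for v in mapping.values()):
                raise ValueError(f"{what} must be non-negative")
            total = sum(mapping.values())
            if not math.isclose(total, 1.0, abs_tol=_TOL):
                raise ValueError(f"{what} must sum to 1 (got {total!r})")
        for sub in SUBCLASSES:
            band_sum = sum(b.weight for b in self.bands if b.subclass == sub)
            if not math.isclose(band_sum, self.class_weights[sub], abs_tol=1e-6):
                raise ValueError(
                    f"band weights for {sub} sum to {band_sum}, "
                    f"expected class weight {self.class_weights[sub]}"
                )

    @property
    def band_width_lu(self) -> dict[str, float]:
        """Mean Gaussian sigma (LU) per subclass, over that subclass's bands."""
        out: dict[str, float] = {}
        for sub in SUBCLASSES:
            sigmas = [b.sigma_lu for b in self.bands if b.subclass == sub]
            if sigmas:
                out[sub] = float(sum(sigmas) / len(sigmas))
        return out


def _preset_from_dict(name: str, raw: dict) -> GenotypePreset:
    bands = tuple(
        Band(b["subclass"], float(b["center_lu"]), float(b["sigma_lu"]), float(b["weight"]))
        for b in raw["bands"]
    )
    return GenotypePreset(
        name=name,
        class_weights={k: float(v) for k, v in raw["class_weights"].items()},
        bands=bands,
        region_fractions={k: float(v) for k, v in raw["region_fractions"].items()},
        gradient_peak_fraction=float(raw.get("gradient_peak_fraction", 6.0)),
        gradient_peak_width=float(raw.get("gradient_peak_width", 1.5)),
    )


def _load_config() -> dict:
    text = resources.files("lipoglo").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def load_presets() -> dict[str, GenotypePreset]:
    """Load the shipped genotype presets (WT, mtp_mut, apoc2_mut, pla2g12b_mut)."""
    cfg = _load_config()
    return {name: _preset_from_dict(name, raw) for name, raw in cfg["presets"].items()}


def get_preset(name: str) -> GenotypePreset:
    presets = load_presets()
    try:
        return presets[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}") from None


def em_reference() -> dict[str, dict[str, float]]:
    """Published EM particle-diameter summaries used as generator defaults.

    Keys are ``wt_fraction4/7/10``; values hold ``mean_nm``, ``sd_nm``, ``n``.
    """
    return _load_config()["em_reference"]
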