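"""Per-individual body measurements and derived morphology.

Jaw area is either measured directly from aerial imagery or modelled as an
isosceles triangle between the bizygomatic width and the rostrum-to-blowhole
length, inflated by a jaw-rotation factor.  Body mass, ventral-groove-blubber
(VGB) length, and wetted surface area come from configurable per-species
power laws; the shipped defaults are calibrations against species-mean
(length, mass) pairs, not literature coefficients, and are flagged as such in
their provenance strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

__all__ = [
    "PowerLaw",
    "SpeciesAllometry",
    "AllometryConfig",
    "WhaleMorphometrics",
    "jaw_area_triangular",
    "allometric_value",
    "complete_morphometrics",
    "DEFAULT_ALLOMETRY",
]

SPECIES = ("minke", "humpback", "fin", "blue")

#: Default jaw-rotation factor: a 5.14% outward-rotation offset.
DEFAULT_O_JAW = 1.0514


class MorphometryError(ValueError):
    """Invalid or missing morphometric input."""


class ConfigurationError(KeyError):
    """Missing or malformed allometric configuration."""


@dataclass(frozen=True)
class PowerLaw:
    """``a * L**b`` with a provenance note."""

    a: float
    b: float
    provenance: str = ""

    def __post_init__(self) -> None:
        import math

        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise ConfigurationError("power-law coefficients must be finite")
        if not 0 < self.b < 4:
            raise ConfigurationError(f"power-law exponent {self.b} outside (0, 4)")

    def __call__(self, L_body: float) -> float:
        return allometric_value(L_body, (self.a, self.b))


@dataclass(frozen=True)
class SpeciesAllometry:
    mass: PowerLaw
    vgb_length: PowerLaw
    wetted_area: PowerLaw


@dataclass(frozen=True)
class AllometryConfig:
    """Per-species power laws plus the jaw-rotation factor."""

    species: Mapping[str, SpeciesAllometry]
    O_jaw: float = DEFAULT_O_JAW

    def __post_init__(self) -> None:
        if self.O_jaw < 1:
            raise ConfigurationError(f"O_jaw must be >= 1, got {self.O_jaw}")

    def for_species(self, name: str) -> SpeciesAllometry:
        try:
            return self.species[name]
        except KeyError:
            raise ConfigurationError(
                f"no allometric coefficients configured for species {name!r}"
            ) from None


def _calibrated(L_mean: float, M_mean: float, b: float, what: str) -> PowerLaw:
    # Exact at the species-mean pair by construction.
    return PowerLaw(
        a=M_mean / L_mean**b,
        b=b,
        provenance=(
            f"calibration default: anchored to species-mean "
            f"(L={L_mean} m, {what}={M_mean}); not a literature coefficient"
        ),
    )


def _default_allometry() -> AllometryConfig:
    # Species-mean (length m, mass kg) anchors; common intraspecific mass
    # exponent 2.74.  VGB length ~0.52 L (throat pouch reaches roughly the
    # umbilicus); wetted area ~0.4 L^2.  All three are calibration defaults.
    anchors = {
        "minke": (7.6, 5961.0),
        "humpback": (11.4, 21464.0),
        "fin": (18.9, 39501.0),
        "blue": (22.3, 64590.0),
    }
    species = {}
    for name, (L, M) in anchors.items():
        species[name] = SpeciesAllometry(
            mass=_calibrated(L, M, 2.74, "M_kg"),
            vgb_length=PowerLaw(0.52, 1.0, "calibration default: VGB ~52% of body length"),
            wetted_area=PowerLaw(0.40, 2.0, "calibration default: S_wet ~0.4 L^2"),
        )
    return AllometryConfig(species=species)


DEFAULT_ALLOMETRY = _default_allometry()


@dataclass
class WhaleMorphometrics:
    """One individual's measured and derived morphology (SI units)."""

    individual_id: str
    species: str
    L_body: float
    w_max: float | None = None
    W_bz: float | None = None
    L_rbh: float | None = None
    A_jaw_direct: float | None = None
    A_jaw_model: float | None = field(default=None)
    M_kg: float | None = field(default=None)
    L_VGB: float | None = field(default=None)
    S_wet: float | None = field(default=None)
    jaw_area_method: str = field(default="")

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise MorphometryError(f"unknown species {self.species!r}")
        for name in ("L_body", "w_max", "W_bz", "L_rbh", "A_jaw_direct",
                     "A_jaw_model", "M_kg", "L_VGB", "S_wet"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise MorphometryError(f"{name} must be strictly positive, got {v}")
        if self.W_bz is not None and self.W_bz >= self.L_body:
            raise MorphometryError("W_bz must be smaller than L_body")
        if self.L_rbh is not None and self.L_rbh >= self.L_body:
            raise MorphometryError("L_rbh must be smaller than L_body")

    @property
    def A_jaw(self) -> float:
        """The working jaw area for engulfment computations."""
        if self.jaw_area_method == "direct":
            assert self.A_jaw_direct is not None
            return self.A_jaw_direct
        if self.jaw_area_method == "model":
            assert self.A_jaw_model is not None
            return self.A_jaw_model
        raise MorphometryError(
            f"no jaw-area method designated for {self.individual_id!r}; "
            "run complete_morphometrics first"
        )


def jaw_area_triangular(W_bz: float, L_rbh: float, O_jaw: float = DEFAULT_O_JAW) -> float:
    """Isosceles-triangle jaw area with outward-rotation correction.

    Parameters
    ----------
    W_bz : float
        Bizygomatic width (m), the triangle base.
    L_rbh : float
        Rostrum-to-blowhole length (m), the triangle height.
    O_jaw : float
        Dimensionless jaw-rotation factor, >= 1.

    Returns
    -------
    float
        Jaw area in m**2: ``(W_bz * L_rbh / 2) * O_jaw``.
    """
    if not W_bz > 0:
        raise MorphometryError(f"W_bz must be strictly positive, got {W_bz}")
    if not L_rbh > 0:
        raise MorphometryError(f"L_rbh must be strictly positive, got {L_rbh}")
    if not O_jaw >= 1:
        raise MorphometryError(f"O_jaw must be >= 1, got {O_jaw}")
    return (W_bz * L_rbh / 2.0) * O_jaw


def allometric_value(L_body: float, coeff: tuple[float, float]) -> float:
    """Evaluate the power law ``a * L_body**b``."""
    if not L_body > 0:
        raise MorphometryError(f"L_body must be strictly positive, got {L_body}")
    a, b = coeff
    return a * L_body**b


def complete_morphometrics(
    raw: WhaleMorphometrics,
    config: AllometryConfig = DEFAULT_ALLOMETRY,
    prefer_direct: bool = True,
) -> WhaleMorphometrics:
    """Fill derived fields and designate the working jaw-area method.

    Direct measurement wins over the triangular model when both are present
    unless ``prefer_direct`` is False.
    """
    allo = config.for_species(raw.species)
    A_model = None
    if raw.W_bz is not None and raw.L_rbh is not None:
        A_model = jaw_area_triangular(raw.W_bz, raw.L_rbh, config.O_jaw)
    if raw.A_jaw_direct is None and A_model is None:
        raise MorphometryError(
            f"{raw.individual_id!r}: need either A_jaw_direct or both (W_bz, L_rbh)"
        )
    if raw.A_jaw_direct is not None and (prefer_direct or A_model is None):
        method = "direct"
    else:
        method = "model"
    return replace(
        raw,
        A_jaw_model=A_model,
        M_kg=allo.mass(raw.L_body),
        L_VGB=allo.vgb_length(raw.L_body),
        S_wet=allo.wetted_area(raw.L_body),
        jaw_area_method=method,
    )
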