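"""Geometric and optical parameter types shared across the package.

All lengths are micrometers (μm) unless a field name says otherwise; the
attenuation coefficient therefore carries μm⁻¹. Unit conversion happens only
at I/O boundaries, never inside the models.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Mapping

__all__ = [
    "ArrayGeometry",
    "EmitterDisk",
    "ObservationPoint",
    "DoseParams",
    "validate_geometry",
    "GeometryError",
]

CANONICAL_LENGTH_UNIT = "um"


class GeometryError(ValueError):
    """A geometric or optical invariant is violated; the message names it."""


@dataclass(frozen=True)
class ArrayGeometry:
    """Discrete microneedle (MN) array layout.

    The default is a 19×19 grid of square-based pyramidal tips with a 300 μm
    base, tips 450–500 μm tall, on a 350 μm center-to-center pitch. The
    50 μm figure sometimes quoted for tip spacing is the edge-to-edge gap
    between adjacent bases: ``pitch_um − base_um``. Pitch is canonical; the
    gap is derived.
    """

    n_rows: int = 19
    n_cols: int = 19
    pitch_um: float = 350.0
    base_um: float = 300.0
    tip_height_um_min: float = 450.0
    tip_height_um_max: float = 500.0
    tip_shape: str = "square_pyramid"
    length_unit: str = CANONICAL_LENGTH_UNIT

    def __post_init__(self) -> None:
        validate_geometry(self)

    @property
    def gap_um(self) -> float:
        """Edge-to-edge gap between adjacent tip bases (50 μm for defaults)."""
        return self.pitch_um - self.base_um

    @property
    def extent_x_um(self) -> float:
        """Lateral extent of the array (columns × pitch)."""
        return self.n_cols * self.pitch_um

    @property
    def extent_y_um(self) -> float:
        return self.n_rows * self.pitch_um

    @property
    def tip_height_um_mid(self) -> float:
        return 0.5 * (self.tip_height_um_min + self.tip_height_um_max)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ArrayGeometry":
        return cls(**dict(d))


def validate_geometry(geom: ArrayGeometry) -> ArrayGeometry:
    """Check every ArrayGeometry invariant, naming the violated one.

    Returns the geometry unchanged when valid.
    """
    if geom.length_unit != CANONICAL_LENGTH_UNIT:
        raise GeometryError(
            f"mixed units: length_unit must be {CANONICAL_LENGTH_UNIT!r}, "
            f"got {geom.length_unit!r}"
        )
    if geom.n_rows < 1 or geom.n_cols < 1:
        raise GeometryError("empty array: n_rows and n_cols must be >= 1")
    if not geom.base_um > 0:
        raise GeometryError("nonpositive base: base_um must be > 0")
    if geom.pitch_um < geom.base_um:
        raise GeometryError(
            "overlapping bases: pitch_um must be >= base_um "
            f"({geom.pitch_um} < {geom.base_um})"
        )
    if not geom.tip_height_um_min > 0:
        raise GeometryError("nonpositive tip height: tip_height_um_min must be > 0")
    if geom.tip_height_um_max < geom.tip_height_um_min:
        raise GeometryError(
            "inverted height range: tip_height_um_max must be >= tip_height_um_min"
        )
    if geom.tip_shape != "square_pyramid":
        raise GeometryError(f"unsupported tip_shape {geom.tip_shape!r}")
    return geom


@dataclass(frozen=True)
class EmitterDisk:
    """Continuum source model: isotropic emitters on a disk.

    Emitters of reference intensity ``I0`` at distance ``r0`` are spread
    uniformly at surface density ``sigma`` (emitters per unit area) over a
    disk of radius ``R``. ``alpha`` is the attenuation coefficient of the
    surrounding medium (μm⁻¹ by convention).
    """

    R: float
    sigma: float = 1.0
    I0: float = 1.0
    r0: float = 1.0
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if not self.R > 0:
            raise GeometryError("disk radius R must be > 0")
        if self.sigma < 0:
            raise GeometryError("emitter density sigma must be >= 0")
        if self.I0 < 0:
            raise GeometryError("reference intensity I0 must be >= 0")
        if not self.r0 > 0:
            raise GeometryError("reference distance r0 must be > 0")
        if self.alpha < 0:
            raise GeometryError("attenuation coefficient alpha must be >= 0")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "EmitterDisk":
        return cls(**dict(d))


@dataclass(frozen=True)
class ObservationPoint:
    """On-axis observation point at axial distance ``rho`` from disk center.

    The closed-form intensity diverges at ρ = 0, so ρ must be positive;
    the models additionally enforce a small ``rho_min`` guard.
    """

    rho: float

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise GeometryError("observation distance rho must be > 0")


@dataclass(frozen=True)
class DoseParams:
    """Irradiance (mW/cm²) and exposure duration (s) for a PDT light dose."""

    irradiance_mw_cm2: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.irradiance_mw_cm2 < 0:
            raise GeometryError("irradiance must be >= 0")
        if self.duration_s < 0:
            raise GeometryError("duration must be >= 0")
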