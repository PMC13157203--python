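"""Synthetic renderer for laser-illuminated microneedle-array photographs.

Emulates the lateral 8-bit RGB photographs of an MN array lit by a green
(543.5 nm) laser and imaged at camera angles between 0° and 90°. The scene
is reduced to a 2-D band pattern sufficient to exercise the downstream
line-profile procedure:

* horizontal bands through tip rows glow uniformly with tip-scattered
  light whose level follows ``tip_law(angle)`` (constant by default — the
  isotropy being demonstrated);
* horizontal bands between tip rows carry light transmitted between the
  tips, following ``gap_law(angle)`` (peaked at 0° with monotone falloff),
  dimmed by a fixed shadow fraction behind each tip column so the tip
  positions on the geometry's pitch are visible in the image;
* both are restricted to the illuminated beam window, outside which a dim
  background remains;
* oblique viewing compresses the horizontal axis by cos(angle), so each
  image carries its own de-projected μm-per-pixel calibration; at steep
  angles adjacent tip columns merge and the downstream quality check fires;
* seeded Gaussian noise is added before clipping and 8-bit quantization.

Ground truth (the law values actually used) is stored alongside every
image, never embedded in the pixels.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import imageio.v3 as iio
import numpy as np

from .geometry import ArrayGeometry

__all__ = [
    "AngularLaw",
    "ConstantLaw",
    "CosPowerLaw",
    "RenderSpec",
    "AngularImage",
    "SaturationWarning",
    "generate_array_image",
    "render_angle_set",
    "load_angle_set",
    "DEFAULT_ANGLES_DEG",
]

DEFAULT_ANGLES_DEG: tuple[float, ...] = (0.0, 24.0, 31.0, 57.0, 77.0)


class SaturationWarning(UserWarning):
    """More than the allowed fraction of beam-window pixels saturated."""


class AngularLaw:
    """Base class for angular intensity laws (green counts vs camera angle)."""

    def __call__(self, angle_deg: float) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def to_dict(self) -> dict[str, Any]:  # pragma: no cover - abstract
        raise NotImplementedError

    @staticmethod
    def from_dict(d: Mapping[str, Any]) -> "AngularLaw":
        kind = d["kind"]
        if kind == "constant":
            return ConstantLaw(level=float(d["level"]))
        if kind == "cos_power":
            return CosPowerLaw(scale=float(d["scale"]), power=float(d["power"]))
        raise ValueError(f"unknown angular law kind {kind!r}")


@dataclass(frozen=True)
class ConstantLaw(AngularLaw):
    """Angle-independent level — an isotropic source."""

    level: float = 120.0

    def __call__(self, angle_deg: float) -> float:
        if self.level < 0:
            raise ValueError("law value must be >= 0")
        return self.level

    def to_dict(self) -> dict[str, Any]:
        return {"kind": "constant", "level": self.level}


@dataclass(frozen=True)
class CosPowerLaw(AngularLaw):
    """scale·cosᵖ(angle): peaked at 0°, strictly decreasing on [0°, 90°)."""

    scale: float = 230.0
    power: float = 4.0

    def __call__(self, angle_deg: float) -> float:
        if self.scale < 0:
            raise ValueError("law value must be >= 0")
        return self.scale * math.cos(math.radians(angle_deg)) ** self.power

    def to_dict(self) -> dict[str, Any]:
        return {"kind": "cos_power", "scale": self.scale, "power": self.power}


@dataclass(frozen=True)
class RenderSpec:
    """Everything needed to render one seeded set of angular images.

    ``um_per_px`` is the head-on (0°) calibration; oblique images compress
    horizontally by cos(angle) and record the corresponding de-projected
    calibration. The beam window defaults to the 2000–4000 μm central
    exposure region. Noise is additive Gaussian in counts, applied before
    quantization; red and blue channels are fixed fractions of green since
    the laser line is green.
    """

    geometry: ArrayGeometry = field(default_factory=ArrayGeometry)
    angles_deg: tuple[float, ...] = DEFAULT_ANGLES_DEG
    um_per_px: float = 10.0
    gap_law: AngularLaw = field(default_factory=CosPowerLaw)
    tip_law: AngularLaw = field(default_factory=ConstantLaw)
    beam_center_um: float = 3000.0
    beam_width_um: float = 2000.0
    background: float = 5.0
    shadow_fraction: float = 0.6
    red_fraction: float = 0.15
    blue_fraction: float = 0.10
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.um_per_px > 0:
            raise ValueError("um_per_px must be > 0")
        for a in self.angles_deg:
            if not (0.0 <= a < 90.0):
                raise ValueError("camera angles must lie in [0°, 90°)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for law, name in ((self.gap_law, "gap_law"), (self.tip_law, "tip_law")):
            for a in self.angles_deg:
                if law(a) < 0:
                    raise ValueError(f"{name} must be >= 0 at all angles")

    def to_dict(self) -> dict[str, Any]:
        return {
            "geometry": self.geometry.to_dict(),
            "angles_deg": list(self.angles_deg),
            "um_per_px": self.um_per_px,
            "gap_law": self.gap_law.to_dict(),
            "tip_law": self.tip_law.to_dict(),
            "beam_center_um": self.beam_center_um,
            "beam_width_um": self.beam_width_um,
            "background": self.background,
            "shadow_fraction": self.shadow_fraction,
            "red_fraction": self.red_fraction,
            "blue_fraction": self.blue_fraction,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RenderSpec":
        d = dict(d)
        d["geometry"] = ArrayGeometry.from_dict(d["geometry"])
        d["angles_deg"] = tuple(d["angles_deg"])
        d["gap_law"] = AngularLaw.from_dict(d["gap_law"])
        d["tip_law"] = AngularLaw.from_dict(d["tip_law"])
        return cls(**d)


@dataclass
class AngularImage:
    """One rendered (or loaded) 8-bit RGB image with its calibration.

    ``um_per_px`` is the de-projected horizontal calibration for *this*
    image, i.e. micrometers of array surface per pixel column; vertical
    calibration is ``um_per_px_y``. ``ground_truth`` holds the gap/tip law
    values used by the renderer.
    """

    pixels: np.ndarray
    angle_deg: float
    um_per_px: float
    um_per_px_y: float
    ground_truth: dict[str, float]
    saturated: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be an H×W×3 array")
        if px.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit (uint8)")
        self.pixels = px


def _green_field(spec: RenderSpec, angle_deg: float) -> tuple[np.ndarray, float]:
    """Noiseless green-channel float field and the de-projected calibration."""
    geom = spec.geometry
    cos_a = math.cos(math.radians(angle_deg))
    um_per_px_x = spec.um_per_px / cos_a  # array-μm spanned by one column
    width = max(1, int(round(geom.extent_x_um / um_per_px_x)))
    height = max(1, int(round(geom.extent_y_um / spec.um_per_px)))

    # de-projected lateral positions (μm): left edge for beam masking (so the
    # illuminated columns align exactly with the analysis window), center for
    # tip-column classification
    u_edge = np.arange(width) * um_per_px_x
    u_center = (np.arange(width) + 0.5) * um_per_px_x
    v = (np.arange(height) + 0.5) * spec.um_per_px

    half_base = geom.base_um / 2.0
    # offset within the pitch cell, relative to the nearest tip center
    du = np.abs((u_center % geom.pitch_um) - geom.pitch_um / 2.0)
    dv = np.abs((v % geom.pitch_um) - geom.pitch_um / 2.0)
    in_tip_col = du <= half_base
    in_tip_row = dv <= half_base

    lo = spec.beam_center_um - spec.beam_width_um / 2.0
    hi = spec.beam_center_um + spec.beam_width_um / 2.0
    in_beam = (u_edge >= lo) & (u_edge < hi)

    gap_level = spec.gap_law(angle_deg)
    tip_level = spec.tip_law(angle_deg)

    g = np.full((height, width), spec.background, dtype=float)
    beam_cols = np.broadcast_to(in_beam, (height, width))
    tip_rows = np.broadcast_to(in_tip_row[:, None], (height, width))
    tip_cols = np.broadcast_to(in_tip_col, (height, width))
    # tip-scattered light glows uniformly along each tip row
    g[beam_cols & tip_rows] = tip_level
    # transmitted light between tip rows, shadowed behind each tip column
    g[beam_cols & ~tip_rows & ~tip_cols] = gap_level
    g[beam_cols & ~tip_rows & tip_cols] = spec.shadow_fraction * gap_level
    return g, um_per_px_x


def generate_array_image(
    spec: RenderSpec,
    angle_deg: float,
    rng: np.random.Generator | None = None,
    saturation_fraction: float = 0.05,
) -> AngularImage:
    """Render one angular image: bands, beam window, noise, 8-bit quantization.

    A fresh generator seeded from ``spec.seed`` and the angle is used unless
    ``rng`` is supplied (``render_angle_set`` passes per-angle spawns of one
    stream). If more than ``saturation_fraction`` of beam-window pixels
    saturate at 255 the image is flagged and a :class:`SaturationWarning`
    is emitted.
    """
    if rng is None:
        ss = np.random.SeedSequence([int(spec.seed), int(round(angle_deg * 1000))])
        rng = np.random.default_rng(ss)
    g, um_per_px_x = _green_field(spec, angle_deg)
    h, w = g.shape
    channels = [g, spec.red_fraction * g, spec.blue_fraction * g]
    # RGB order: red, green, blue
    stack = np.stack([channels[1], channels[0], channels[2]], axis=-1)
    if spec.noise_sd > 0:
        stack = stack + rng.normal(0.0, spec.noise_sd, size=stack.shape)
    quant = np.clip(np.rint(stack), 0, 255).astype(np.uint8)

    lo = spec.beam_center_um - spec.beam_width_um / 2.0
    hi = spec.beam_center_um + spec.beam_width_um / 2.0
    u = np.arange(w) * um_per_px_x
    beam_cols = (u >= lo) & (u < hi)
    beam_green = quant[:, beam_cols, 1]
    saturated = False
    if beam_green.size:
        frac = float(np.mean(beam_green == 255))
        if frac > saturation_fraction:
            saturated = True
            warnings.warn(
                f"{frac:.1%} of beam-window pixels saturated at angle "
                f"{angle_deg}°",
                SaturationWarning,
            )
    return AngularImage(
        pixels=quant,
        angle_deg=float(angle_deg),
        um_per_px=um_per_px_x,
        um_per_px_y=spec.um_per_px,
        ground_truth={
            "gap": spec.gap_law(angle_deg),
            "tip": spec.tip_law(angle_deg),
            "background": spec.background,
        },
        saturated=saturated,
    )


def render_angle_set(
    spec: RenderSpec, out_dir: str | Path | None = None
) -> list[AngularImage]:
    """Render one image per angle with independent noise from one seeded stream.

    With ``out_dir`` set, writes ``angle_<deg>.png`` files plus a
    ``manifest.json`` echoing the spec, the seed, and per-angle ground
    truth and calibration.
    """
    streams = np.random.SeedSequence(int(spec.seed)).spawn(max(len(spec.angles_deg), 1))
    images = [
        generate_array_image(spec, angle, rng=np.random.default_rng(ss))
        for angle, ss in zip(spec.angles_deg, streams)
    ]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        entries = []
        for img in images:
            name = f"angle_{img.angle_deg:g}.png"
            iio.imwrite(out / name, img.pixels)
            entries.append(
                {
                    "file": name,
                    "angle_deg": img.angle_deg,
                    "um_per_px": img.um_per_px,
                    "um_per_px_y": img.um_per_px_y,
                    "ground_truth": img.ground_truth,
                    "saturated": img.saturated,
                }
            )
        manifest = {"spec": spec.to_dict(), "seed": spec.seed, "images": entries}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return images


def load_angle_set(in_dir: str | Path) -> tuple[RenderSpec, list[AngularImage]]:
    """Read a rendered set back from PNG files plus its manifest."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    spec = RenderSpec.from_dict(manifest["spec"])
    images = []
    for e in manifest["images"]:
        px = iio.imread(in_dir / e["file"])
        images.append(
            AngularImage(
                pixels=np.asarray(px, dtype=np.uint8),
                angle_deg=float(e["angle_deg"]),
                um_per_px=float(e["um_per_px"]),
                um_per_px_y=float(e["um_per_px_y"]),
                ground_truth=dict(e["ground_truth"]),
                saturated=bool(e.get("saturated", False)),
            )
        )
    return spec, images
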