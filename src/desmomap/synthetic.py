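"""Synthetic single-molecule localization data for paired desmosomal plaques.

A desmosome imaged en face in a super-resolution reconstruction appears as
two parallel, line-like plaques — one per cell — mirror-symmetric about the
junction midline.  This module builds such ground-truth geometries, draws
localizations from them (uniform along each plaque, Gaussian transverse
spread for plaque thickness, isotropic Gaussian localization noise, uniform
Poisson background), and renders localization tables into pixel images.

Emitter photophysics (blinking, repeated localizations of one fluorophore)
is deliberately collapsed into a single localizations-per-plaque count: the
downstream pipeline measures geometry, not stoichiometry.

Coordinates are nanometres in a fixed image frame: origin top-left,
x to the right, y increasing downward.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DataError, GeometryError
from .io import RenderedImage

__all__ = [
    "GroundTruthJunction",
    "SimulationParams",
    "make_junction",
    "sample_localizations",
    "render",
    "simulate_desmosome",
    "write_ground_truth",
]


@dataclass(frozen=True)
class GroundTruthJunction:
    """Geometry of one simulated desmosome.

    The two plaque centre-lines are parallel to the long axis (``orientation``
    degrees from +x toward +y) and offset by ``±separation/2`` along the unit
    normal, so the junction is mirror-symmetric across its midline.
    """

    center: tuple[float, float]
    orientation: float          # degrees, long axis, in [0, 180)
    separation: float           # true plaque-to-plaque distance, nm
    plaque_length: float        # extent along the long axis, nm
    plaque_thickness: float     # Gaussian transverse spread of emitters, nm

    @property
    def axis(self) -> np.ndarray:
        """Unit vector along the junction long axis."""
        a = math.radians(self.orientation)
        return np.array([math.cos(a), math.sin(a)])

    @property
    def normal(self) -> np.ndarray:
        """Unit normal of the long axis (the cross-junction direction)."""
        a = math.radians(self.orientation)
        return np.array([-math.sin(a), math.cos(a)])

    def plaque_centers(self) -> np.ndarray:
        """(2, 2) array: centre point of each plaque line (offset ±separation/2)."""
        c = np.asarray(self.center, dtype=float)
        off = 0.5 * self.separation * self.normal
        return np.stack([c + off, c - off])


@dataclass(frozen=True)
class SimulationParams:
    """Stochastic sampling parameters for one simulated field of view."""

    localization_precision: float = 15.0   # nm, std of isotropic noise per localization
    localizations_per_plaque: int = 200
    background_density: float = 2.0        # localizations per µm²
    field_size: float = 2000.0             # nm, square field centred on the junction
    seed: int = 0

    def __post_init__(self):
        if self.localization_precision < 0:
            raise DataError("localization_precision must be >= 0")
        if self.localizations_per_plaque < 0:
            raise DataError("localizations_per_plaque must be >= 0")
        if self.background_density < 0:
            raise DataError("background_density must be >= 0")
        if self.field_size <= 0:
            raise DataError("field_size must be > 0")


def make_junction(
    separation: float,
    plaque_length: float,
    orientation: float = 0.0,
    center: tuple[float, float] = (0.0, 0.0),
    plaque_thickness: float = 15.0,
) -> GroundTruthJunction:
    """Construct a mirror-symmetric paired-plaque geometry.

    Parameters
    ----------
    separation
        True plaque-to-plaque distance in nm; must be > 0.
    plaque_length
        Plaque extent along the junction long axis in nm; must be > 0.
    orientation
        In-plane angle of the long axis in degrees; reduced to [0, 180).
    center
        Midpoint of the junction in nm.
    plaque_thickness
        Std of the Gaussian transverse emitter spread about each plaque
        line, nm; must be >= 0.
    """
    if not separation > 0:
        raise GeometryError(f"separation must be > 0, got {separation}")
    if not plaque_length > 0:
        raise GeometryError(f"plaque_length must be > 0, got {plaque_length}")
    if plaque_thickness < 0:
        raise GeometryError(f"plaque_thickness must be >= 0, got {plaque_thickness}")
    return GroundTruthJunction(
        center=(float(center[0]), float(center[1])),
        orientation=float(orientation) % 180.0,
        separation=float(separation),
        plaque_length=float(plaque_length),
        plaque_thickness=float(plaque_thickness),
    )


def sample_localizations(
    junction: GroundTruthJunction,
    params: SimulationParams,
    return_truth: bool = False,
):
    """Draw a localization table from a ground-truth junction.

    For each plaque, ``localizations_per_plaque`` emitters are placed
    uniformly along the plaque line, displaced transversely by
    N(0, plaque_thickness²); each resulting localization is then displaced
    isotropically by N(0, precision²).  Background localizations are uniform
    over the square field with expected count
    ``background_density × field area``.

    Returns a :class:`pandas.DataFrame` with the canonical columns
    ``id, frame, x_nm, y_nm, precision_nm, channel``.  Plaque membership is
    recorded in a ``source`` column (1, 2, or 0 for background).  With
    ``return_truth=True`` also returns the (n, 2) true emitter positions
    (background truth is its own sampled position).
    """
    rng = np.random.default_rng(params.seed)
    n = params.localizations_per_plaque
    cx, cy = junction.center
    axis, normal = junction.axis, junction.normal

    emitters = []
    sources = []
    for k, pc in enumerate(junction.plaque_centers(), start=1):
        t = rng.uniform(-junction.plaque_length / 2, junction.plaque_length / 2, size=n)
        w = (
            rng.normal(0.0, junction.plaque_thickness, size=n)
            if junction.plaque_thickness > 0
            else np.zeros(n)
        )
        emitters.append(pc[None, :] + t[:, None] * axis[None, :] + w[:, None] * normal[None, :])
        sources.append(np.full(n, k, dtype=int))

    half = params.field_size / 2
    area_um2 = (params.field_size / 1000.0) ** 2
    n_bg = rng.poisson(params.background_density * area_um2)
    bg = np.column_stack(
        [rng.uniform(cx - half, cx + half, n_bg), rng.uniform(cy - half, cy + half, n_bg)]
    )
    emitters.append(bg)
    sources.append(np.zeros(n_bg, dtype=int))

    truth = np.concatenate(emitters) if emitters else np.empty((0, 2))
    source = np.concatenate(sources)
    if params.localization_precision > 0 and len(truth):
        xy = truth + rng.normal(0.0, params.localization_precision, size=truth.shape)
    else:
        xy = truth.copy()

    table = pd.DataFrame(
        {
            "id": np.arange(len(xy)),
            "frame": np.arange(len(xy)),
            "x_nm": xy[:, 0],
            "y_nm": xy[:, 1],
            "precision_nm": np.full(len(xy), float(params.localization_precision)),
            "channel": np.zeros(len(xy), dtype=int),
            "source": source,
        }
    )
    if return_truth:
        return table, truth
    return table


def render(
    locs: pd.DataFrame,
    pixel_size: float = 4.0,
    mode: str = "histogram",
    origin: Optional[tuple[float, float]] = None,
    shape: Optional[tuple[int, int]] = None,
) -> RenderedImage:
    """Render a localization table into a pixel image.

    ``histogram`` mode adds 1 to the pixel containing each localization;
    ``gaussian`` mode adds a unit-integral Gaussian kernel whose width is the
    localization's precision, so in either mode the image total equals the
    localization count up to boundary truncation.

    ``origin`` is the nm coordinate of the top-left corner of pixel (0, 0);
    if omitted, origin and shape are chosen to cover the data with a small
    margin.  An empty table with explicit ``origin``/``shape`` yields an
    all-zero image.
    """
    if pixel_size <= 0:
        raise DataError(f"pixel_size must be > 0, got {pixel_size}")
    if mode not in ("histogram", "gaussian"):
        raise DataError(f"unknown render mode {mode!r}")

    x = np.asarray(locs["x_nm"], dtype=float) if len(locs) else np.empty(0)
    y = np.asarray(locs["y_nm"], dtype=float) if len(locs) else np.empty(0)

    if origin is None or shape is None:
        if len(locs) == 0:
            raise DataError("cannot infer image extent from an empty table; pass origin and shape")
        margin = 5 * pixel_size
        x0 = np.floor((x.min() - margin) / pixel_size) * pixel_size
        y0 = np.floor((y.min() - margin) / pixel_size) * pixel_size
        ncols = int(np.ceil((x.max() + margin - x0) / pixel_size))
        nrows = int(np.ceil((y.max() + margin - y0) / pixel_size))
        origin = (x0, y0)
        shape = (nrows, ncols)

    nrows, ncols = shape
    x0, y0 = origin
    data = np.zeros((nrows, ncols), dtype=np.float32)

    if mode == "histogram":
        cols = np.floor((x - x0) / pixel_size).astype(int)
        rows = np.floor((y - y0) / pixel_size).astype(int)
        ok = (rows >= 0) & (rows < nrows) & (cols >= 0) & (cols < ncols)
        np.add.at(data, (rows[ok], cols[ok]), 1.0)
    else:
        prec = np.asarray(locs["precision_nm"], dtype=float) if len(locs) else np.empty(0)
        for xi, yi, si in zip(x, y, prec):
            sigma_px = max(si, 1e-6) / pixel_size
            ci = (xi - x0) / pixel_size - 0.5
            ri = (yi - y0) / pixel_size - 0.5
            r = max(1, int(np.ceil(4 * sigma_px)))
            r0, r1 = int(np.floor(ri)) - r, int(np.floor(ri)) + r + 1
            c0, c1 = int(np.floor(ci)) - r, int(np.floor(ci)) + r + 1
            rr = np.arange(max(r0, 0), min(r1, nrows))
            cc = np.arange(max(c0, 0), min(c1, ncols))
            if len(rr) == 0 or len(cc) == 0:
                continue
            gr = np.exp(-0.5 * ((rr - ri) / sigma_px) ** 2)
            gc = np.exp(-0.5 * ((cc - ci) / sigma_px) ** 2)
            stamp = np.outer(gr, gc)
            # unit integral over the untruncated stamp
            full_r = np.exp(-0.5 * ((np.arange(r0, r1) - ri) / sigma_px) ** 2)
            full_c = np.exp(-0.5 * ((np.arange(c0, c1) - ci) / sigma_px) ** 2)
            stamp /= np.outer(full_r, full_c).sum()
            data[rr[0] : rr[-1] + 1, cc[0] : cc[-1] + 1] += stamp.astype(np.float32)

    return RenderedImage(data=data, pixel_size=float(pixel_size), origin=(float(x0), float(y0)))


def simulate_desmosome(
    separation: float,
    params: SimulationParams,
    plaque_length: float = 600.0,
    orientation: Optional[float] = None,
    plaque_thickness: float = 15.0,
    pixel_size: float = 4.0,
    mode: str = "histogram",
):
    """Simulate one desmosome end to end: geometry → localizations → image.

    If ``orientation`` is None it is drawn uniformly in [0°, 180°) from the
    same seeded stream.  The image covers the full square field.  Returns
    ``(junction, table, image)``.
    """
    rng = np.random.default_rng(params.seed)
    if orientation is None:
        orientation = float(rng.uniform(0.0, 180.0))
    center = (params.field_size / 2, params.field_size / 2)
    junction = make_junction(
        separation, plaque_length, orientation, center, plaque_thickness
    )
    # derive an independent sub-seed so orientation draw and sampling decouple
    sub = SimulationParams(
        localization_precision=params.localization_precision,
        localizations_per_plaque=params.localizations_per_plaque,
        background_density=params.background_density,
        field_size=params.field_size,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    table = sample_localizations(junction, sub)
    npx = int(round(params.field_size / pixel_size))
    image = render(table, pixel_size, mode=mode, origin=(0.0, 0.0), shape=(npx, npx))
    return junction, table, image


def write_ground_truth(junction: GroundTruthJunction, path) -> None:
    """Write the ground-truth geometry as a JSON sidecar."""
    Path(path).write_text(json.dumps(asdict(junction), indent=2) + "\n")
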