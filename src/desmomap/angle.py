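"""Aligned-angle geometric model of desmoplakin orientation in the plaque.

Desmoplakin (DP) is a head–rod–tail protein.  Its three splice isoforms
(DPI, DPIa, DPII) differ only in rod length: 888, 448 and 290 residues.
Rotary-shadowing EM put full-length DPI at 162 nm with 16 nm head and tail
domains, giving a 130 nm rod; assuming rod length scales linearly with
residue count, the rise per residue is 130/888 nm and the other isoform
lengths follow.

Super-resolution imaging measures the plaque-to-plaque (PtP) distance of a
labelled domain: twice its distance from the junction midline.  If DP lies
at angle θ to the membrane plane with its head at the measured head
position, the tail sits ``L·sin θ`` farther from the midline, so

    θ = arcsin( ((PtP_tail − PtP_head) / 2) / L )

which is the model inverted here.  Uncertainty on θ is propagated from the
group standard deviations of the two PtP measurements by a first-order
delta method, with a Monte-Carlo resampling alternative for cross-checking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, GeometryError

__all__ = [
    "IsoformSpec",
    "AngleResult",
    "DEFAULT_ISOFORMS",
    "rod_length_from_total",
    "isoform_length",
    "angle_of_alignment",
    "propagate_angle_sd",
    "monte_carlo_angle_sd",
    "to_scale_model",
]

#: axial rise per rod residue, nm — anchored so that DPI (888-aa rod)
#: has a 130 nm rod and a 162 nm total length
RISE_PER_AA = 130.0 / 888.0


@dataclass(frozen=True)
class IsoformSpec:
    """Dimensions of one desmoplakin isoform."""

    name: str
    rod_aa: int                     # residue count of the coiled-coil rod
    head_size: float = 16.0         # nm
    tail_size: float = 16.0         # nm
    rise_per_aa: float = RISE_PER_AA  # nm per residue

    def __post_init__(self):
        if self.rod_aa < 0:
            raise DataError("rod_aa must be >= 0")
        if self.head_size < 0 or self.tail_size < 0:
            raise DataError("head and tail sizes must be >= 0")
        if self.rise_per_aa <= 0:
            raise DataError("rise_per_aa must be > 0")


DEFAULT_ISOFORMS: dict[str, IsoformSpec] = {
    "DPI": IsoformSpec("DPI", rod_aa=888),
    "DPIa": IsoformSpec("DPIa", rod_aa=448),
    "DPII": IsoformSpec("DPII", rod_aa=290),
}


@dataclass(frozen=True)
class AngleResult:
    """Angle of alignment for one isoform, with the inputs that produced it."""

    theta: float                    # degrees, in [0, 90]
    length: float                   # nm, full head-to-tail protein length
    half_ptp_tail: float            # nm
    half_ptp_head: float            # nm
    theta_sd: Optional[float] = None  # degrees, propagated
    name: str = ""


def rod_length_from_total(total_length: float, head_size: float, tail_size: float) -> float:
    """Rod length as total protein length minus head and tail domains (nm)."""
    rod = total_length - head_size - tail_size
    if rod <= 0:
        raise GeometryError(
            f"non-positive rod length: {total_length} - {head_size} - {tail_size} = {rod}"
        )
    return rod


def isoform_length(spec: IsoformSpec) -> float:
    """Full head-to-tail length L = rod_aa × rise_per_aa + head + tail (nm).

    Kept at full precision; round only at report time.
    """
    return spec.rod_aa * spec.rise_per_aa + spec.head_size + spec.tail_size


def angle_of_alignment(
    ptp_tail: float, ptp_head: float, length: float, name: str = ""
) -> AngleResult:
    """Angle between the DP long axis and the membrane plane, degrees.

    ``θ = arcsin(((ptp_tail − ptp_head)/2) / length)``.  The tail must be at
    least as far from the midline as the head (the rod points inward), and
    the transverse offset cannot exceed the protein length.
    """
    if ptp_head < 0:
        raise DataError("ptp_head must be >= 0")
    if ptp_tail < ptp_head:
        raise GeometryError(
            "ptp_tail < ptp_head: the tail cannot be membrane-proximal to the head"
        )
    if length <= 0:
        raise DataError("length must be > 0")
    arg = ((ptp_tail - ptp_head) / 2.0) / length
    if arg > 1.0:
        raise GeometryError(
            f"transverse offset {(ptp_tail - ptp_head) / 2:.1f} nm exceeds protein "
            f"length {length:.1f} nm (arcsine argument {arg:.3f} > 1)"
        )
    return AngleResult(
        theta=math.degrees(math.asin(arg)),
        length=float(length),
        half_ptp_tail=ptp_tail / 2.0,
        half_ptp_head=ptp_head / 2.0,
        name=name,
    )


def propagate_angle_sd(
    sd_tail: float, sd_head: float, theta: float, length: float
) -> float:
    """First-order (delta-method) s.d. of θ, degrees.

    With θ = arcsin((t − h)/(2L)) and independent errors on the two PtP
    group means, sd_θ = sqrt((sd_t/2)² + (sd_h/2)²) / (L·cos θ).
    """
    if sd_tail < 0 or sd_head < 0:
        raise DataError("standard deviations must be >= 0")
    if length <= 0:
        raise DataError("length must be > 0")
    if theta >= 90.0:
        raise GeometryError("cannot propagate uncertainty at θ >= 90° (cos θ = 0)")
    sd_offset = math.hypot(sd_tail / 2.0, sd_head / 2.0)
    return math.degrees(sd_offset / (length * math.cos(math.radians(theta))))


def monte_carlo_angle_sd(
    ptp_tail: float,
    ptp_head: float,
    sd_tail: float,
    sd_head: float,
    length: float,
    n_draws: int = 100_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo s.d. of θ: resample the two PtP values from normal
    distributions, recompute θ per draw, return the sample s.d. in degrees.

    Draws whose geometry is infeasible (tail inside head, offset beyond L)
    are clipped to the feasible boundary, matching how a bounded estimate
    would be reported.
    """
    rng = np.random.default_rng(seed)
    t = rng.normal(ptp_tail, sd_tail, n_draws)
    h = rng.normal(ptp_head, sd_head, n_draws)
    arg = np.clip((t - h) / (2.0 * length), 0.0, 1.0)
    theta = np.degrees(np.arcsin(arg))
    return float(theta.std(ddof=1))


def solve_isoform(
    spec: IsoformSpec,
    ptp_tail: float,
    ptp_head: float,
    sd_tail: Optional[float] = None,
    sd_head: Optional[float] = None,
) -> AngleResult:
    """Convenience: length from the isoform spec, then θ (and its s.d. if
    group standard deviations are given)."""
    length = isoform_length(spec)
    res = angle_of_alignment(ptp_tail, ptp_head, length, name=spec.name)
    if sd_tail is not None and sd_head is not None:
        res = replace(
            res, theta_sd=propagate_angle_sd(sd_tail, sd_head, res.theta, length)
        )
    return res


def to_scale_model(
    specs: Sequence[IsoformSpec], results: Sequence[AngleResult]
) -> pd.DataFrame:
    """Plot-ready segment coordinates for a to-scale schematic.

    For each isoform and each side of the midline (side = ±1): the head
    anchor at (0, side·half_ptp_head) and the tail end at
    (L·cos θ, side·half_ptp_tail).  Transverse (y) coordinates are distances
    from the junction midline; x runs along the junction.
    """
    if len(specs) != len(results):
        raise DataError(
            f"got {len(specs)} isoform specs but {len(results)} angle results"
        )
    rows = []
    for spec, res in zip(specs, results):
        L = isoform_length(spec)
        dx = L * math.cos(math.radians(res.theta))
        for side in (1, -1):
            rows.append(
                {
                    "isoform": spec.name,
                    "side": side,
                    "head_x_nm": 0.0,
                    "head_y_nm": side * res.half_ptp_head,
                    "tail_x_nm": dx,
                    "tail_y_nm": side * res.half_ptp_tail,
                    "length_nm": L,
                    "theta_deg": res.theta,
                }
            )
    return pd.DataFrame(rows)
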