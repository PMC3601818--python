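"""Vulval-muscle shape quantification from traced polygons.

Muscle outlines are planar polygons traced on a confocal projection, in
micrometres.  The quantities of interest are the polygon area, the vm2/vm1
size ratio S_vm2/S_vm1, and the intersection angle between the muscle axis
(midpoint of the body-wall attachment line -> vm2 tip) and the axis of the
vulval slit, folded into [0, 90] degrees because an intersection of two
lines has no orientation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from shapely.geometry import LinearRing, Polygon as _ShapelyPolygon

__all__ = ["MusclePolygon", "polygon_area", "size_ratio", "intersection_angle"]


@dataclass(frozen=True)
class MusclePolygon:
    """One traced muscle outline with its angle landmarks.

    ``vertices`` are ordered (x, y) coordinates in um.  ``attachment_midpoint``
    is the midpoint of the line connecting the muscle to the body wall;
    ``tip`` the distal cell tip; ``slit_axis`` a direction vector of the
    vulval opening.  Landmarks may be omitted when only the area is needed.
    """

    vertices: np.ndarray
    muscle_id: str = ""
    attachment_midpoint: Optional[tuple[float, float]] = None
    tip: Optional[tuple[float, float]] = None
    slit_axis: Optional[tuple[float, float]] = None
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("vertices must be an (n>=3, 2) coordinate array")
        if not np.all(np.isfinite(v)):
            raise ValueError("vertices must be finite")
        object.__setattr__(self, "vertices", v)
        if self.pixel_size_um == 1.0:
            warnings.warn(
                "pixel_size_um left at 1.0; areas are in px^2 unless pixels are 1 um",
                stacklevel=3,
            )

    @property
    def vertices_um(self) -> np.ndarray:
        return self.vertices * self.pixel_size_um


def polygon_area(p: MusclePolygon) -> float:
    """Shoelace area in um^2, positive regardless of vertex orientation.

    Self-intersecting outlines are rejected because the shoelace sum would
    silently cancel overlapping lobes.
    """
    verts = p.vertices_um
    ring = LinearRing(verts)
    if not ring.is_simple:
        raise ValueError("polygon is self-intersecting")
    poly = _ShapelyPolygon(verts)
    if poly.area == 0.0:
        raise ValueError("degenerate (zero-area) polygon")
    return float(poly.area)


def size_ratio(vm2_area: float, vm1_area: float) -> float:
    """Relative size of vm2 to vm1, S_vm2 / S_vm1."""
    if vm1_area <= 0:
        raise ValueError("vm1 area must be positive")
    return vm2_area / vm1_area


def intersection_angle(p: MusclePolygon) -> float:
    """Angle (degrees) between the muscle axis and the vulval slit axis.

    The muscle axis runs from the attachment midpoint to the tip.  The
    unsigned intersection angle is folded into [0, 90]; exactly parallel
    axes report 0.
    """
    if p.attachment_midpoint is None or p.tip is None or p.slit_axis is None:
        raise ValueError("intersection_angle requires attachment_midpoint, tip and slit_axis")
    axis = np.asarray(p.tip, float) - np.asarray(p.attachment_midpoint, float)
    slit = np.asarray(p.slit_axis, float)
    na, ns = np.linalg.norm(axis), np.linalg.norm(slit)
    if na == 0:
        raise ValueError("tip coincides with attachment midpoint")
    if ns == 0:
        raise ValueError("slit axis must be a nonzero vector")
    cosang = abs(float(np.dot(axis, slit)) / (na * ns))
    return math.degrees(math.acos(min(1.0, cosang)))
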