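"""Cross-section geometry of succulent leaves.

Both study species build their leaves from five concentric tissue layers
(outside-in: epidermis with bladder cells, chlorenchyma, peripheral net
of vascular bundles, hydrenchyma, central vascular strand).  Terete
(near-circular) cross-sections are measured along the minor/major
diameters; triquetrous (triangular) ones along the three interior angle
bisectors r1–r3 and one side bisector r4.  Layer thickness is the outer
intercept minus the intercept of the adjacent inner tissue.

Whole-leaf dimensions are handled in mm, tissue-level ones in µm; the
converters are explicit so a unit mix-up raises instead of silently
mis-scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError, DataError

__all__ = [
    "LAYERS",
    "um_to_mm",
    "mm_to_um",
    "tissue_thickness",
    "stack_thicknesses",
    "bisector_lines",
    "shrinkage",
    "shrinkage_correction",
    "aspect_ratio",
    "sa_vol",
    "TereteCrossSection",
    "TriquetrousCrossSection",
    "CellGeometry",
    "ShrinkageRecord",
]

#: tissue layers, outside-in
LAYERS = ("ebc", "epi", "chl", "nvb", "hyd", "cvs")


def um_to_mm(x: float) -> float:
    return x / 1000.0


def mm_to_um(x: float) -> float:
    return x * 1000.0


def tissue_thickness(outer_radius_um: float, inner_radius_um: float) -> float:
    """Layer thickness (µm): outer tissue radius minus the radius of the
    adjacent inner tissue."""
    if inner_radius_um < 0:
        raise DataError("radii must be non-negative")
    if inner_radius_um > outer_radius_um:
        raise DataError(
            f"inner radius {inner_radius_um} exceeds outer {outer_radius_um}"
        )
    return outer_radius_um - inner_radius_um


def stack_thicknesses(radii_um: Sequence[float]) -> np.ndarray:
    """Thicknesses of consecutive layers from outside-in radii.

    ``sum(thicknesses) + innermost radius == outermost radius`` holds by
    construction (telescoping).
    """
    r = np.asarray(radii_um, dtype=float)
    if len(r) < 2:
        raise DataError("need at least two radii")
    if np.any(np.diff(r) > 0):
        raise DataError("radii must be non-increasing from outside in")
    return -np.diff(r)


# ---------------------------------------------------------------------------
# triangle measurement lines

def _seg_intersection(p, d, a, b):
    """Parameter t >= 0 where ray p + t*d crosses segment ab, or None."""
    r = np.asarray(b) - np.asarray(a)
    denom = d[0] * r[1] - d[1] * r[0]
    if abs(denom) < 1e-14:
        return None
    ap = np.asarray(a) - np.asarray(p)
    t = (ap[0] * r[1] - ap[1] * r[0]) / denom
    s = (ap[0] * d[1] - ap[1] * d[0]) / denom
    if t > 1e-12 and -1e-9 <= s <= 1 + 1e-9:
        return t
    return None


def bisector_lines(
    vertices: np.ndarray, r4_side: int = 0
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Measurement lines of a triangular cross-section.

    ``r1``–``r3`` run from each vertex along the interior angle bisector
    to the opposite side (the foot divides that side in the ratio of the
    adjacent side lengths).  ``r4`` is the side bisector: the segment
    from the midpoint of side ``r4_side`` (the side opposite vertex
    ``r4_side``), perpendicular to it, to the far triangle boundary.

    Returns ``{name: (start, end)}`` with points in input units.
    """
    v = np.asarray(vertices, dtype=float)
    if v.shape != (3, 2):
        raise DataError("vertices must be a (3, 2) array")
    e1, e2 = v[1] - v[0], v[2] - v[0]
    area2 = abs(e1[0] * e2[1] - e1[1] * e2[0])
    if area2 < 1e-12:
        raise DataError("degenerate (collinear) triangle")

    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for k in range(3):
        A = v[k]
        B, C = v[(k + 1) % 3], v[(k + 2) % 3]
        c = np.linalg.norm(B - A)  # |AB|
        b = np.linalg.norm(C - A)  # |AC|
        foot = B + (c / (b + c)) * (C - B)  # angle-bisector theorem
        out[f"r{k + 1}"] = (A.copy(), foot)

    i = r4_side % 3
    a, b_ = v[(i + 1) % 3], v[(i + 2) % 3]
    mid = 0.5 * (a + b_)
    side = b_ - a
    normal = np.array([-side[1], side[0]])
    normal /= np.linalg.norm(normal)
    centroid = v.mean(axis=0)
    if np.dot(normal, centroid - mid) < 0:
        normal = -normal
    ts = []
    for j in range(3):
        if j == i:
            continue
        t = _seg_intersection(mid, normal, v[(j + 1) % 3], v[(j + 2) % 3])
        if t is not None:
            ts.append(t)
    if not ts:
        raise DataError("side bisector does not reach the far boundary")
    out["r4"] = (mid, mid + min(ts) * normal)
    return out


# ---------------------------------------------------------------------------
# shrinkage, aspect ratio, surface-to-volume

def shrinkage(fresh: float, embedded: float) -> float:
    """Percentage shrinkage of an embedded section relative to fresh."""
    if fresh <= 0:
        raise DataError("fresh dimension must be positive")
    return 100.0 * (fresh - embedded) / fresh


def shrinkage_correction(embedded: float, gamma_percent: float) -> float:
    """Recover the fresh dimension: ``embedded / (1 - gamma/100)``."""
    if gamma_percent >= 100:
        raise DataError("shrinkage of 100% or more is not invertible")
    return embedded / (1.0 - gamma_percent / 100.0)


def aspect_ratio(d_1: float, d_2: float) -> float:
    """Ratio of the larger to the smaller cross-sectional diameter."""
    if d_1 <= 0 or d_2 <= 0:
        raise DataError("diameters must be positive")
    hi, lo = max(d_1, d_2), min(d_1, d_2)
    return hi / lo


def sa_vol(shape: str, **dimensions) -> float:
    """Surface-area-to-volume ratio (1/length unit) of an idealized leaf.

    ``shape="cone"`` takes ``radius`` and ``height`` (lateral plus base
    area over volume); ``shape="tetrahedron"`` takes ``vertices`` as a
    (4, 3) array (sum of face areas over volume).
    """
    if shape == "cone":
        r = dimensions.get("radius")
        h = dimensions.get("height")
        if r is None or h is None or r <= 0 or h <= 0:
            raise ConfigError("cone needs positive radius and height")
        slant = math.hypot(r, h)
        area = math.pi * r * (r + slant)
        volume = math.pi * r * r * h / 3.0
        return area / volume
    if shape == "tetrahedron":
        v = np.asarray(dimensions.get("vertices"), dtype=float)
        if v.shape != (4, 3):
            raise ConfigError("tetrahedron needs a (4, 3) vertices array")
        e1, e2, e3 = v[1] - v[0], v[2] - v[0], v[3] - v[0]
        volume = abs(np.dot(e1, np.cross(e2, e3))) / 6.0
        if volume < 1e-14:
            raise DataError("degenerate tetrahedron")
        faces = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
        area = sum(
            0.5 * np.linalg.norm(np.cross(v[j] - v[i], v[k] - v[i]))
            for i, j, k in faces
        )
        return float(area / volume)
    raise ConfigError(f"unknown shape {shape!r}")


# ---------------------------------------------------------------------------
# cross-section containers

@dataclass(frozen=True)
class TereteCrossSection:
    """Five concentric layers of a (near-)circular leaf cross-section.

    ``outer_radius_a``/``outer_radius_b`` map each layer to its outer
    radius (µm) along the minor (a) and major (b) diameter.  The model is
    centro-symmetric, so the thickness along an axis is the radius
    difference to the adjacent inner tissue on that axis.
    """

    outer_radius_a: Mapping[str, float]
    outer_radius_b: Mapping[str, float]
    d_a_mm: float
    d_b_mm: float
    layers: tuple[str, ...] = LAYERS

    def __post_init__(self) -> None:
        if self.d_a_mm <= 0 or self.d_b_mm <= 0:
            raise DataError("leaf diameters must be positive")
        for radii in (self.outer_radius_a, self.outer_radius_b):
            vals = [radii[la] for la in self.layers if la in radii]
            if len(vals) < 2:
                raise DataError("need radii for at least two layers")
            if any(v <= 0 for v in vals):
                raise DataError("radii must be positive")
            if any(x <= y for x, y in zip(vals, vals[1:])):
                raise DataError("radii must strictly decrease inward")

    def thickness(self, layer: str, axis: str) -> float:
        """Thickness (µm) of ``layer`` along axis ``"a"`` or ``"b"``."""
        radii = {"a": self.outer_radius_a, "b": self.outer_radius_b}[axis]
        present = [la for la in self.layers if la in radii]
        k = present.index(layer)
        outer = radii[layer]
        inner = radii[present[k + 1]] if k + 1 < len(present) else 0.0
        return tissue_thickness(outer, inner)

    def thickness_table(self) -> dict[str, float]:
        out = {}
        for axis in ("a", "b"):
            radii = {"a": self.outer_radius_a, "b": self.outer_radius_b}[axis]
            for la in self.layers:
                if la in radii:
                    out[f"t_{la},{axis}"] = self.thickness(la, axis)
        return out


@dataclass(frozen=True)
class TriquetrousCrossSection:
    """Layer intercepts of a triangular cross-section along r1–r4.

    ``intercepts`` maps line name ("r1".."r4") to {layer: outer intercept
    distance from the line's start, µm}, decreasing inward.
    """

    vertices_um: np.ndarray
    intercepts: Mapping[str, Mapping[str, float]]
    r4_side: int = 0
    layers: tuple[str, ...] = LAYERS

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices_um, dtype=float)
        object.__setattr__(self, "vertices_um", v)
        bisector_lines(v, self.r4_side)  # validates the triangle
        for line, radii in self.intercepts.items():
            vals = [radii[la] for la in self.layers if la in radii]
            if any(x <= y for x, y in zip(vals, vals[1:])):
                raise DataError(
                    f"intercepts along {line} must strictly decrease inward"
                )

    def measurement_lines(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        return bisector_lines(self.vertices_um, self.r4_side)

    def thickness(self, layer: str, line: str) -> float:
        radii = self.intercepts[line]
        present = [la for la in self.layers if la in radii]
        k = present.index(layer)
        outer = radii[layer]
        inner = radii[present[k + 1]] if k + 1 < len(present) else 0.0
        return tissue_thickness(outer, inner)

    def thickness_table(self) -> dict[str, float]:
        return {
            f"t_{la},{line}": self.thickness(la, line)
            for line in self.intercepts
            for la in self.layers if la in self.intercepts[line]
        }


@dataclass(frozen=True)
class CellGeometry:
    """Median parenchyma cell geometry (µm)."""

    d_c_um: float  # cell diameter
    t_cw_um: float  # cell-wall thickness
    d_major_um: float = None
    d_minor_um: float = None

    def __post_init__(self) -> None:
        if not (self.d_c_um > 0 and self.t_cw_um > 0):
            raise DataError("cell diameter and wall thickness must be positive")
        if self.t_cw_um >= 0.1 * self.d_c_um:
            # catches mm-vs-µm mix-ups: real walls are far thinner than cells
            raise DataError(
                "cell wall thickness is not small relative to the cell "
                "diameter; check units (µm expected)"
            )

    @property
    def aspect_ratio(self) -> float:
        if self.d_major_um is None or self.d_minor_um is None:
            raise DataError("cross-sectional diameters not set")
        return aspect_ratio(self.d_major_um, self.d_minor_um)


@dataclass(frozen=True)
class ShrinkageRecord:
    """Fresh vs embedded dimension (mm) with percentage shrinkage."""

    fresh_mm: float
    embedded_mm: float

    def __post_init__(self) -> None:
        self.gamma_percent  # validates

    @property
    def gamma_percent(self) -> float:
        g = shrinkage(self.fresh_mm, self.embedded_mm)
        if g >= 100:
            raise DataError("shrinkage >= 100% implies a vanished sample")
        return g
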