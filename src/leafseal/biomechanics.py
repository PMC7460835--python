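"""Mechanical properties from tensile tests and turgor-based moduli.

Entire leaves and single tissues are characterized by uniaxial tensile
tests: the elastic modulus is the slope of the best linear region of the
stress-strain trace, the tensile strength its maximum stress, Poisson's
ratio the negative slope of lateral versus axial strain.  Parenchyma
(hydrenchyma, chlorenchyma) cannot be gripped, so its modulus is derived
from cell geometry and turgor through a linear-in-turgor relation

    E = k_w * E_cw * (t_cw / d_c) + k_P * P

with a cell-wall-network term (wall modulus ``E_cw`` scaled by the
wall-thickness-to-cell-diameter ratio) and a turgor-stiffening term
proportional to the turgor pressure ``P``.  See docs/methods.md for how
the default coefficients ``k_w = 4`` and ``k_P = 27/8`` were fixed.

All stresses and moduli are in MPa; strains and Poisson's ratio are
dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .morphometry import CellGeometry
from .stats import significance_stars

__all__ = [
    "StressStrainTrace",
    "TissueMechanics",
    "ComparisonRow",
    "LinearRegionError",
    "elastic_modulus",
    "tensile_strength",
    "poisson_ratio",
    "nilsson_parenchyma_modulus",
    "comparison_table",
    "round_half_away",
]


class LinearRegionError(DataError):
    """No sufficiently linear region found in a stress-strain trace."""

    def __init__(self, message: str, best_r2: float = math.nan):
        super().__init__(message)
        self.best_r2 = best_r2


@dataclass(frozen=True)
class StressStrainTrace:
    """A tensile-test curve: strain (dimensionless) vs stress (MPa)."""

    strain: np.ndarray
    stress_mpa: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.strain, dtype=float)
        s = np.asarray(self.stress_mpa, dtype=float)
        object.__setattr__(self, "strain", e)
        object.__setattr__(self, "stress_mpa", s)
        if e.shape != s.shape or e.ndim != 1:
            raise DataError("strain and stress must be equal-length vectors")
        if len(e) == 0:
            raise DataError("empty stress-strain trace")
        if not np.all(np.isfinite(s)) or not np.all(np.isfinite(e)):
            raise DataError("non-finite values in trace")
        if np.any(np.diff(e) < 0):
            raise DataError("strain must be non-decreasing")
        if abs(e[0]) > 1e-9:
            raise DataError("trace must start at zero strain")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"strain": self.strain,
                             "stress_mpa": self.stress_mpa})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "StressStrainTrace":
        df = pd.read_csv(path)
        missing = {"strain", "stress_mpa"} - set(df.columns)
        if missing:
            raise DataError(f"trace table missing columns {sorted(missing)}")
        return cls(strain=df["strain"].to_numpy(),
                   stress_mpa=df["stress_mpa"].to_numpy())


def elastic_modulus(
    trace: StressStrainTrace,
    min_window_frac: float = 0.2,
    r2_min: float = 0.9,
) -> float:
    """Slope (MPa) of the best linear region of the pre-peak trace.

    All contiguous windows covering at least ``min_window_frac`` of the
    pre-peak points are scored by R-squared; the window with the highest
    R-squared wins, ties going to the longest (then earliest) window, so
    the result is deterministic.
    """
    e, s = trace.strain, trace.stress_mpa
    peak = int(np.argmax(s))
    e, s = e[: peak + 1], s[: peak + 1]
    n = len(e)
    if n < 5:
        raise DataError("need at least 5 pre-peak points")
    w_min = max(3, int(math.ceil(min_window_frac * n)))

    best = None  # (r2, length, -start, slope)
    for w in range(w_min, n + 1):
        for start in range(0, n - w + 1):
            xe, ys = e[start:start + w], s[start:start + w]
            xm, ym = xe.mean(), ys.mean()
            sxx = np.sum((xe - xm) ** 2)
            if sxx <= 0:
                continue
            sxy = np.sum((xe - xm) * (ys - ym))
            syy = np.sum((ys - ym) ** 2)
            if syy <= 0:
                continue
            slope = sxy / sxx
            r2 = (sxy * sxy) / (sxx * syy)
            key = (round(r2, 12), w, -start)
            if best is None or key > best[0]:
                best = (key, slope)
    if best is None:
        raise LinearRegionError("trace has no window with finite variance")
    (r2, _, _), slope = best
    if r2 < r2_min:
        raise LinearRegionError(
            f"best linear region has R^2 = {r2:.4f} < {r2_min}", best_r2=r2
        )
    return float(slope)


def tensile_strength(trace: StressStrainTrace) -> float:
    """Maximum stress (MPa) attained before failure."""
    return float(np.max(trace.stress_mpa))


def poisson_ratio(
    axial_strain: Sequence[float], lateral_strain: Sequence[float]
) -> float:
    """Negative slope of the lateral-vs-axial strain regression."""
    ax = np.asarray(axial_strain, dtype=float)
    lat = np.asarray(lateral_strain, dtype=float)
    if ax.shape != lat.shape or ax.ndim != 1:
        raise DataError("axial and lateral strain series must match in length")
    if len(ax) < 2 or np.any(np.diff(ax) <= 0):
        raise DataError("axial strain must be strictly increasing")
    slope = np.polyfit(ax, lat, 1)[0]
    return float(-slope)


#: default coefficients of the linear-in-turgor parenchyma relation
NILSSON_WALL_COEFF = 4.0
NILSSON_TURGOR_COEFF = 27.0 / 8.0


def nilsson_parenchyma_modulus(
    cell: CellGeometry,
    P_mpa: float,
    nu: float,
    E_cw_mpa: float,
    *,
    wall_coeff: float = NILSSON_WALL_COEFF,
    turgor_coeff: float = NILSSON_TURGOR_COEFF,
) -> float:
    """Parenchyma elastic modulus (MPa) from cell geometry and turgor.

    Linear in the turgor ``P``; at ``P = 0`` only the cell-wall-network
    term ``wall_coeff * E_cw * t_cw / d_c`` remains.  ``nu`` (tissue
    Poisson's ratio) is validated against the physical range; across the
    measured range of the study species its influence is below the
    reporting precision and the default coefficients are constants (the
    coefficients are keyword-tunable).
    """
    if not (0.0 <= nu <= 0.5):
        raise DataError(f"Poisson's ratio {nu} outside [0, 0.5]")
    if P_mpa < 0:
        raise DataError("turgor must be non-negative")
    if E_cw_mpa <= 0:
        raise DataError("cell-wall modulus must be positive")
    return (wall_coeff * E_cw_mpa * cell.t_cw_um / cell.d_c_um
            + turgor_coeff * P_mpa)


# ---------------------------------------------------------------------------
# interspecific comparison tables

def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (what printed ratio tables use), e.g.
    0.4545 -> 0.45 and 0.665 -> 0.67 at two digits."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TissueMechanics:
    """Bundle of mechanical descriptors for one tissue or whole leaf."""

    E_mpa: Optional[float] = None
    sigma_max_mpa: Optional[float] = None
    nu: Optional[float] = None
    P_mpa: Optional[float] = None
    E_cw_mpa: Optional[float] = None

    def __post_init__(self) -> None:
        for name, lo, hi in (("E_mpa", 0, math.inf),
                             ("sigma_max_mpa", 0, math.inf),
                             ("nu", 0, 0.5), ("P_mpa", 0, math.inf),
                             ("E_cw_mpa", 0, math.inf)):
            v = getattr(self, name)
            if v is not None and not (lo <= v <= hi):
                raise DataError(f"{name} = {v} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class ComparisonRow:
    """One property row of an interspecific comparison table."""

    property_name: str
    median_1: float
    median_2: float
    se_1: Optional[float] = None
    se_2: Optional[float] = None
    n_1: Optional[int] = None
    n_2: Optional[int] = None
    p: Optional[float] = None

    @property
    def ratio(self) -> float:
        if self.median_2 == 0:
            raise DataError(
                f"{self.property_name}: zero denominator median"
            )
        return round_half_away(self.median_1 / self.median_2, 2)

    @property
    def stars(self) -> str:
        return significance_stars(self.p) if self.p is not None else "-"


def comparison_table(rows: Sequence[ComparisonRow]) -> pd.DataFrame:
    """Table of per-species medians with their ratio and significance."""
    records = []
    for row in rows:
        records.append({
            "property": row.property_name,
            "median_1": row.median_1, "se_1": row.se_1, "n_1": row.n_1,
            "median_2": row.median_2, "se_2": row.se_2, "n_2": row.n_2,
            "ratio": row.ratio,
            "stars": row.stars,
        })
    return pd.DataFrame(records)
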