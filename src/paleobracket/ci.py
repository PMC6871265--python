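"""Frequentist soft-maximum estimation from stratigraphic ranges.

Two bases are supported.  The *extant* basis treats the observed range as
running from the FAD to the present, with gap sizes between successive
localities exponentially distributed under random fossilization and
recovery; the confidence bound is

    T_C = FAD * (1 - C)^(-1/n).

The *range* basis conditions on the last (youngest) occurrence, which makes
the gaps Dirichlet-distributed and changes the exponent:

    T_C = R * [(1 - C)^(-1/(n-1)) - 1] + FAD.

Extant lineages default to the extant basis and extinct ones to the range
basis; callers may override.  Axis-transformed and nonuniform-recovery
variants map the problem onto a coordinate where recovery is uniform, apply
the same formulas, and map the bound back to Ma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .core import LineageRecord, RecoveryCurve

__all__ = [
    "CIResult",
    "AgeAxisMap",
    "ci_extant",
    "ci_range",
    "ci_for_record",
    "unbiased_origin",
    "ml_corrected_origin",
    "ci_transformed",
    "ci_nonuniform",
]


@dataclass
class CIResult:
    """A one-sided confidence bound T_C on a time of origin."""

    t_c: float
    confidence: float
    n: int
    fad: float
    basis: str            # "extant" | "range"
    axis: str = "time"    # "time" | "transformed"
    bounded: bool = True

    def __post_init__(self) -> None:
        if self.bounded and self.t_c < self.fad:
            raise ValueError(f"T_C ({self.t_c}) below the FAD used ({self.fad})")


def _check_confidence(c: float) -> None:
    if not (0.0 <= c < 1.0):
        raise ValueError(f"confidence must satisfy 0 <= C < 1, got {c}")


def ci_extant(fad: float, n: int, c: float) -> CIResult:
    """Confidence bound for a lineage whose range extends to the present."""
    _check_confidence(c)
    if fad <= 0:
        raise ValueError(f"FAD must be positive, got {fad}")
    if n < 1:
        raise ValueError(f"need n >= 1 localities, got {n}")
    t_c = fad * (1.0 - c) ** (-1.0 / n)
    return CIResult(t_c=t_c, confidence=c, n=n, fad=fad, basis="extant")


def ci_range(fad: float, r: float, n: int, c: float) -> CIResult:
    """Confidence bound conditioning on the observed range endpoints."""
    _check_confidence(c)
    if n < 2:
        raise ValueError(f"range basis needs n >= 2 localities, got {n}")
    if r <= 0:
        raise ValueError(f"range length must be positive, got {r}")
    t_c = r * ((1.0 - c) ** (-1.0 / (n - 1)) - 1.0) + fad
    return CIResult(t_c=t_c, confidence=c, n=n, fad=fad, basis="range")


def _resolve_basis(record: LineageRecord, basis: Optional[str]) -> str:
    if basis is None or basis == "auto":
        return "extant" if record.extant else "range"
    if basis not in ("extant", "range"):
        raise ValueError(f"unknown basis {basis!r}")
    return basis


def ci_for_record(record: LineageRecord, c: float, basis: Optional[str] = None,
                  endpoint: str = "mid") -> CIResult:
    """Apply the basis-appropriate confidence bound to a lineage record."""
    basis = _resolve_basis(record, basis)
    fad = record.fad_value(endpoint)
    if basis == "extant":
        return ci_extant(fad, record.n, c)
    r = fad - record.lad_value(endpoint)
    return ci_range(fad, r, record.n, c)


def unbiased_origin(record: LineageRecord, endpoint: str = "mid",
                    basis: Optional[str] = None) -> float:
    """Unbiased point estimate of the origin: FAD plus the average gap size.

    Extant basis: FAD + FAD/n.  Range basis: FAD + R/(n-1).
    """
    basis = _resolve_basis(record, basis)
    fad = record.fad_value(endpoint)
    n = record.n
    if basis == "extant":
        return fad + fad / n
    if n < 2:
        raise ValueError(f"range basis needs n >= 2 localities, got {n}")
    r = fad - record.lad_value(endpoint)
    return fad + r / (n - 1)


def ml_corrected_origin(fad: float, n: int) -> float:
    """Finite-sample-corrected maximum-likelihood origin, FAD * (n+1)/n."""
    if fad <= 0:
        raise ValueError(f"FAD must be positive, got {fad}")
    if n < 1:
        raise ValueError(f"need n >= 1 localities, got {n}")
    return fad * (n + 1) / n


class AgeAxisMap:
    """Monotone piecewise-linear mapping between age (Ma) and a proxy axis.

    Built from (age, axis) control points through dated horizons, e.g.
    cumulative sandstone thickness.  Beyond the control points the edge
    segments are extrapolated linearly.  Both coordinates must be strictly
    increasing together.
    """

    def __init__(self, points: Sequence[Tuple[float, float]]):
        pts = sorted(set((float(a), float(x)) for a, x in points))
        ages = [p[0] for p in pts]
        axes = [p[1] for p in pts]
        if len(pts) < 2:
            raise ValueError("need at least two (age, axis) control points")
        if len(set(ages)) != len(ages):
            raise ValueError("age -> axis mapping is not a function: duplicate ages")
        if any(b <= a for a, b in zip(axes, axes[1:])):
            raise ValueError("age -> axis mapping must be strictly monotone")
        self._ages = np.asarray(ages)
        self._axes = np.asarray(axes)

    @classmethod
    def identity(cls) -> "AgeAxisMap":
        return _IdentityMap()

    @classmethod
    def from_record(cls, record: LineageRecord, endpoint: str = "mid",
                    anchor_present: bool = True) -> "AgeAxisMap":
        """Build the mapping from the record's dated, axis-positioned horizons."""
        pts = []
        for occ in record.occurrences:
            if occ.axis_position is None:
                raise ValueError(
                    f"occurrence at {occ.locality_id!r} lacks an axis_position"
                )
            pts.append((occ.age.endpoint(endpoint), occ.axis_position))
        if anchor_present:
            pts.append((0.0, 0.0))
        return cls(pts)

    def _interp(self, x: float, xs: np.ndarray, ys: np.ndarray) -> float:
        i = int(np.clip(np.searchsorted(xs, x, side="right") - 1, 0, xs.size - 2))
        slope = (ys[i + 1] - ys[i]) / (xs[i + 1] - xs[i])
        return float(ys[i] + (x - xs[i]) * slope)

    def forward(self, age: float) -> float:
        return self._interp(age, self._ages, self._axes)

    def inverse(self, axis: float) -> float:
        return self._interp(axis, self._axes, self._ages)


class _IdentityMap(AgeAxisMap):
    """Exact pass-through mapping (axis == age)."""

    def __init__(self):
        self._ages = np.array([0.0, 1.0])
        self._axes = np.array([0.0, 1.0])

    def forward(self, age: float) -> float:
        return age

    def inverse(self, axis: float) -> float:
        return axis


def ci_transformed(record: LineageRecord, c: float,
                   axis_map: Optional[AgeAxisMap] = None,
                   basis: Optional[str] = None,
                   endpoint: str = "mid") -> CIResult:
    """Confidence bound computed on a transformed axis, mapped back to Ma.

    The CI formula is applied in the axis coordinate (where deposition, and
    hence recovery potential, is taken to be uniform), and the resulting
    bound is mapped back to an age.  With the identity mapping this equals
    the untransformed CI exactly.
    """
    basis = _resolve_basis(record, basis)
    if axis_map is None:
        axis_map = AgeAxisMap.from_record(record, endpoint=endpoint,
                                          anchor_present=(basis == "extant"))
    fad_age = record.fad_value(endpoint)
    fad_axis = axis_map.forward(fad_age)
    n = record.n
    if basis == "extant":
        bound_axis = ci_extant(fad_axis, n, c).t_c
    else:
        lad_axis = axis_map.forward(record.lad_value(endpoint))
        bound_axis = ci_range(fad_axis, fad_axis - lad_axis, n, c).t_c
    t_c = axis_map.inverse(bound_axis)
    return CIResult(t_c=t_c, confidence=c, n=n, fad=fad_age, basis=basis,
                    axis="transformed")


def ci_nonuniform(record: LineageRecord, curve: RecoveryCurve, c: float,
                  basis: Optional[str] = None,
                  endpoint: str = "mid") -> CIResult:
    """Confidence bound under a nonuniform recovery-potential curve.

    With G(t) the cumulative recovery potential from the present back to age
    t, the extant-basis bound solves (G(FAD)/G(T))^n = 1 - C; the range
    basis applies the range formula in G coordinates (where recovery is
    uniform) and maps back.  Reduces to the uniform-recovery formulas when
    the curve is constant.

    If the curve holds too little recovery potential older than the FAD for
    the bound to exist, the result is flagged ``bounded=False`` with
    ``t_c = inf`` rather than raising.
    """
    _check_confidence(c)
    basis = _resolve_basis(record, basis)
    fad = record.fad_value(endpoint)
    n = record.n
    g_fad = curve.cumulative(fad)
    if g_fad <= 0:
        raise ValueError("recovery curve has zero potential younger than the FAD")
    if basis == "extant":
        g_target = g_fad * (1.0 - c) ** (-1.0 / n)
    else:
        if n < 2:
            raise ValueError(f"range basis needs n >= 2 localities, got {n}")
        g_lad = curve.cumulative(record.lad_value(endpoint))
        g_r = g_fad - g_lad
        if g_r <= 0:
            raise ValueError("zero recovery potential within the observed range")
        g_target = g_fad + g_r * ((1.0 - c) ** (-1.0 / (n - 1)) - 1.0)
    if g_target > curve.total_potential:
        return CIResult(t_c=math.inf, confidence=c, n=n, fad=fad, basis=basis,
                        axis="transformed", bounded=False)
    t_c = float(curve.invert_cumulative(g_target))
    return CIResult(t_c=t_c, confidence=c, n=n, fad=fad, basis=basis,
                    axis="transformed")
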