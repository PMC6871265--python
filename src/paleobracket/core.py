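"""Domain types for fossil-based divergence-time bracketing.

Conventions
-----------
Ages are in Ma (million years) before present; larger values are older and
the present is 0.  A lineage's first appearance datum (FAD) is its oldest
occurrence, its last appearance datum (LAD) the youngest.  Range lengths are
measured FAD minus LAD for extinct lineages and FAD minus 0 (the present)
for extant ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np

__all__ = [
    "AgeInterval",
    "FossilOccurrence",
    "LineageRecord",
    "RecoveryCurve",
    "BracketEstimate",
    "UltrametricTopology",
]

#: Valid endpoint selectors for evaluating an :class:`AgeInterval`.
ENDPOINTS = ("older", "younger", "mid")


@dataclass(frozen=True)
class AgeInterval:
    """An age with dating uncertainty, as a closed interval in Ma.

    ``older >= younger >= 0``; a point age has ``older == younger``.
    """

    older: float
    younger: float

    def __post_init__(self) -> None:
        if not (self.older >= self.younger >= 0.0):
            raise ValueError(
                f"invalid age interval: need older >= younger >= 0, "
                f"got older={self.older}, younger={self.younger}"
            )

    @classmethod
    def point(cls, age: float) -> "AgeInterval":
        return cls(older=age, younger=age)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.older + self.younger)

    @property
    def width(self) -> float:
        return self.older - self.younger

    @property
    def is_point(self) -> bool:
        return self.older == self.younger

    def endpoint(self, which: str) -> float:
        """Return the ``older``, ``younger`` or ``mid`` value of the interval."""
        if which == "older":
            return self.older
        if which == "younger":
            return self.younger
        if which == "mid":
            return self.midpoint
        raise ValueError(f"unknown endpoint {which!r}; expected one of {ENDPOINTS}")


@dataclass(frozen=True)
class FossilOccurrence:
    """A single fossil collection assigned to a lineage.

    ``axis_position`` is an optional nonnegative coordinate in user units
    (e.g. cumulative rock thickness) used for axis-transformed confidence
    intervals.  ``apomorphy_documented`` records whether the specimen shows
    a diagnostic derived character, which gates its use as a minimum-age
    constraint.
    """

    taxon_id: str
    lineage_id: str
    locality_id: str
    age: AgeInterval
    horizon_id: Optional[str] = None
    region: Optional[str] = None
    axis_position: Optional[float] = None
    apomorphy_documented: bool = False
    voucher: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.locality_id:
            raise ValueError("locality_id must be nonempty")
        if self.axis_position is not None and self.axis_position < 0:
            raise ValueError(f"axis_position must be >= 0, got {self.axis_position}")


def _oldest_key(occ: FossilOccurrence) -> tuple:
    return (occ.age.older, occ.age.younger)


def _youngest_key(occ: FossilOccurrence) -> tuple:
    return (occ.age.younger, occ.age.older)


@dataclass(frozen=True)
class LineageRecord:
    """A lineage's fossil occurrences together with derived range summaries.

    The locality count ``n`` counts distinct horizons: distinct
    ``horizon_id`` when every occurrence carries one, otherwise distinct
    ``locality_id``.  This is the exponent of the stratigraphic
    confidence-interval formulas.
    """

    lineage_id: str
    extant: bool
    occurrences: tuple

    def __init__(self, lineage_id: str, extant: bool,
                 occurrences: Iterable[FossilOccurrence]):
        occs = tuple(occurrences)
        if not occs:
            raise ValueError(f"lineage {lineage_id!r} has no occurrences")
        for occ in occs:
            if occ.lineage_id != lineage_id:
                raise ValueError(
                    f"occurrence of {occ.lineage_id!r} in record {lineage_id!r}"
                )
        object.__setattr__(self, "lineage_id", lineage_id)
        object.__setattr__(self, "extant", bool(extant))
        object.__setattr__(self, "occurrences", occs)

    @property
    def oldest_occurrence(self) -> FossilOccurrence:
        return max(self.occurrences, key=_oldest_key)

    @property
    def youngest_occurrence(self) -> FossilOccurrence:
        return min(self.occurrences, key=_youngest_key)

    @property
    def fad(self) -> AgeInterval:
        """Age interval of the oldest occurrence (first appearance datum)."""
        return self.oldest_occurrence.age

    @property
    def lad(self) -> AgeInterval:
        """Age interval of the youngest occurrence (last appearance datum)."""
        return self.youngest_occurrence.age

    @property
    def n(self) -> int:
        """Number of distinct fossiliferous horizons (fallback: localities)."""
        if all(occ.horizon_id for occ in self.occurrences):
            return len({occ.horizon_id for occ in self.occurrences})
        return len({occ.locality_id for occ in self.occurrences})

    def fad_value(self, endpoint: str = "mid") -> float:
        return self.fad.endpoint(endpoint)

    def lad_value(self, endpoint: str = "mid") -> float:
        return self.lad.endpoint(endpoint)

    def range_span(self, endpoint: str = "mid",
                   basis: Optional[str] = None) -> float:
        """Observed stratigraphic range R, in Ma.

        FAD - LAD on the range basis (default for extinct lineages);
        FAD - 0 on the extant basis (the range extends to the present).
        ``basis`` overrides the extant-flag default, e.g. to condition an
        extant lineage's analysis on its observed fossil range.
        """
        if basis is None:
            basis = "extant" if self.extant else "range"
        if basis == "extant":
            return self.fad_value(endpoint)
        if basis != "range":
            raise ValueError(f"unknown basis {basis!r}")
        r = self.fad_value(endpoint) - self.lad_value(endpoint)
        if r < 0:
            raise ValueError(
                f"negative range for {self.lineage_id!r} at endpoint {endpoint!r}"
            )
        return r


class RecoveryCurve:
    """Piecewise-constant relative fossil-recovery potential vs. age.

    Defined on ``[breakpoints[0], breakpoints[-1]]`` with
    ``breakpoints[0] == 0`` (the present).  ``rates[i]`` applies on
    ``[breakpoints[i], breakpoints[i+1]]``.  Outside the defined span the
    potential is zero, so the cumulative potential saturates at
    :attr:`total_potential` — a confidence bound that would need more
    potential than exists is reported as unbounded by the CI routines.
    """

    def __init__(self, breakpoints: Sequence[float], rates: Sequence[float]):
        bp = np.asarray(breakpoints, dtype=float)
        r = np.asarray(rates, dtype=float)
        if bp.ndim != 1 or bp.size < 2:
            raise ValueError("need at least two breakpoints")
        if r.size != bp.size - 1:
            raise ValueError(
                f"need len(rates) == len(breakpoints) - 1, "
                f"got {r.size} and {bp.size}"
            )
        if bp[0] != 0.0:
            raise ValueError(f"breakpoints must start at 0, got {bp[0]}")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly ascending")
        if np.any(r < 0):
            raise ValueError("rates must be nonnegative")
        if not np.any(r > 0):
            raise ValueError("at least one rate must be positive")
        self.breakpoints = bp
        self.rates = r
        self._cum = np.concatenate([[0.0], np.cumsum(r * np.diff(bp))])

    @classmethod
    def constant(cls, t_max: float, rate: float = 1.0) -> "RecoveryCurve":
        return cls([0.0, t_max], [rate])

    @property
    def t_max(self) -> float:
        return float(self.breakpoints[-1])

    @property
    def total_potential(self) -> float:
        return float(self._cum[-1])

    @property
    def is_constant(self) -> bool:
        return bool(np.all(self.rates == self.rates[0]))

    def cumulative(self, t):
        """Cumulative recovery potential G(t) from the present back to age t."""
        t = np.asarray(t, dtype=float)
        tc = np.clip(t, 0.0, self.t_max)
        idx = np.clip(
            np.searchsorted(self.breakpoints, tc, side="right") - 1,
            0, self.rates.size - 1,
        )
        g = self._cum[idx] + self.rates[idx] * (tc - self.breakpoints[idx])
        return g if g.ndim else float(g)

    def invert_cumulative(self, g):
        """Oldest-age inverse of G; values above the total potential map to inf.

        Within flat (zero-rate) segments the youngest age attaining g is
        returned.
        """
        g = np.asarray(g, dtype=float)
        idx = np.clip(
            np.searchsorted(self._cum, g, side="right") - 1,
            0, self.rates.size - 1,
        )
        rate = self.rates[idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(
                rate > 0,
                self.breakpoints[idx] + (g - self._cum[idx]) / np.where(rate > 0, rate, 1.0),
                self.breakpoints[idx],
            )
        t = np.where(g > self.total_potential, np.inf, t)
        t = np.where(g < 0, np.nan, t)
        return t if t.ndim else float(t)


@dataclass
class BracketEstimate:
    """A minimum constraint plus soft maximum at confidence C, with a point estimate."""

    min_age: float
    soft_max_age: float
    confidence: float
    point_estimate: float
    method: str
    notes: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.confidence < 1.0):
            raise ValueError(f"confidence must be in (0, 1), got {self.confidence}")
        if not (self.min_age <= self.point_estimate <= self.soft_max_age):
            raise ValueError(
                f"need min <= point <= soft max, got "
                f"{self.min_age}, {self.point_estimate}, {self.soft_max_age}"
            )


class UltrametricTopology:
    """A rooted ultrametric tree with relative depths (tips 0, root 1).

    Branch lengths are rescaled on construction so the root-to-tip depth is
    exactly 1; the input must be ultrametric within ``tol`` (measured on the
    normalized depths).
    """

    def __init__(self, tree: dendropy.Tree, tol: float = 1e-9):
        self._tree = tree
        leaves = list(tree.leaf_node_iter())
        if not leaves:
            raise ValueError("tree has no leaves")

        root = tree.seed_node
        if len(leaves) == 1 and leaves[0] is root:
            # Degenerate single-tip newick like "A:3;" — dendropy parses the
            # branch as the seed edge.  Treat the branch as the one path, the
            # tip at depth 0 and the (implicit) root at depth 1.
            label = self._node_label(root)
            self._depths = {label: 0.0}
            self._parent_depths = {label: 1.0}
            self._tip_labels = [label]
            self._height = root.edge.length or 1.0
            return

        for edge in tree.preorder_edge_iter():
            if edge.head_node is not root and edge.length is None:
                raise ValueError("all branches must have lengths")

        root_dist = {root: 0.0}
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            root_dist[node] = root_dist[node.parent_node] + node.edge.length

        height = max(root_dist[leaf] for leaf in leaves)
        if height <= 0:
            raise ValueError("tree has zero height")
        spread = (height - min(root_dist[leaf] for leaf in leaves)) / height
        if spread > tol:
            raise ValueError(
                f"tree is not ultrametric: relative tip-depth spread "
                f"{spread:.3e} exceeds tolerance {tol:.1e}"
            )

        self._height = height
        self._depths = {}
        self._parent_depths = {}
        depth_of = {node: (height - d) / height for node, d in root_dist.items()}
        for node in tree.preorder_node_iter():
            label = self._node_label(node)
            if label is None:
                continue
            if label in self._depths:
                raise ValueError(f"duplicate node label {label!r}")
            self._depths[label] = depth_of[node]
            parent = node.parent_node
            self._parent_depths[label] = depth_of[parent] if parent is not None else 1.0
        self._tip_labels = [self._node_label(leaf) for leaf in leaves]

    @staticmethod
    def _node_label(node) -> Optional[str]:
        if node.taxon is not None and node.taxon.label:
            return node.taxon.label
        return node.label or None

    @classmethod
    def from_newick(cls, source: str, tol: float = 1e-9) -> "UltrametricTopology":
        """Build from a newick string or a path to a newick file."""
        import os

        if os.path.exists(source):
            tree = dendropy.Tree.get(path=source, schema="newick")
        else:
            tree = dendropy.Tree.get(data=source, schema="newick")
        return cls(tree, tol=tol)

    @property
    def tip_labels(self) -> list:
        return list(self._tip_labels)

    @property
    def labels(self) -> list:
        return sorted(self._depths)

    def depth(self, label: str) -> float:
        """Relative depth of the labeled node (0 = tips, 1 = root)."""
        try:
            return self._depths[label]
        except KeyError:
            raise KeyError(
                f"no node labeled {label!r}; known labels: {self.labels}"
            ) from None

    def stem_depth(self, label: str) -> float:
        """Relative depth of the node subtending the labeled branch."""
        try:
            return self._parent_depths[label]
        except KeyError:
            raise KeyError(
                f"no node labeled {label!r}; known labels: {self.labels}"
            ) from None
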