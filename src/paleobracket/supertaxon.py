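"""Combine multiple FADs into one super-lineage via relative branch depths.

Each calibration fossil's FAD is divided by the relative depth (0 = tips,
1 = root) of the oldest position its lineage's branch permits, yielding an
implied root age.  The implied positions are then treated as localities of
a single lineage running from the root to the present, and the extant-basis
confidence interval brackets the root age.  An internally inconsistent FAD
— one whose implied root age exceeds the bound supported by the others —
can be flagged and removed before bracketing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from .ci import ci_extant
from .core import BracketEstimate, UltrametricTopology

__all__ = ["ProjectedFad", "project_fads", "supertaxon_bracket",
           "flag_inconsistent_fads"]

log = logging.getLogger("paleobracket")


@dataclass(frozen=True)
class ProjectedFad:
    """A FAD mapped onto the super-lineage axis."""

    lineage_id: str
    fad: float
    attach_depth: float
    implied_root_age: float

    def __post_init__(self) -> None:
        if not (0.0 < self.attach_depth <= 1.0):
            raise ValueError(
                f"attach depth must be in (0, 1], got {self.attach_depth}"
            )
        if self.implied_root_age < self.fad:
            raise ValueError("implied root age cannot be younger than the FAD")


def project_fads(tree: UltrametricTopology,
                 fads: Union[Mapping[str, float], Sequence[Tuple[str, float]]],
                 attachment: str = "stem") -> List[ProjectedFad]:
    """Project per-lineage FADs onto the root lineage.

    ``attachment`` selects the oldest permissible position of each fossil:
    ``"stem"`` (default, conservative) uses the depth of the node subtending
    the lineage's branch; ``"crown"`` uses the depth of the branch's own
    node, which is undefined (zero) for tips.

    Output is sorted by implied root age descending, ties broken by lineage
    label for determinism.
    """
    if attachment not in ("stem", "crown"):
        raise ValueError(f"unknown attachment {attachment!r}")
    items = fads.items() if isinstance(fads, Mapping) else fads
    projections = []
    for lineage_id, fad in items:
        if fad <= 0:
            raise ValueError(f"FAD for {lineage_id!r} must be positive, got {fad}")
        if attachment == "stem":
            depth = tree.stem_depth(lineage_id)
        else:
            depth = tree.depth(lineage_id)
            if depth <= 0:
                raise ValueError(
                    f"crown attachment is undefined for tip {lineage_id!r} "
                    "(zero depth); use stem attachment"
                )
        projections.append(ProjectedFad(
            lineage_id=lineage_id, fad=float(fad), attach_depth=depth,
            implied_root_age=float(fad) / depth,
        ))
    projections.sort(key=lambda p: (-p.implied_root_age, p.lineage_id))
    return projections


def supertaxon_bracket(projections: Sequence[ProjectedFad], c: float = 0.95,
                       calibration_lineage: Optional[str] = None,
                       ) -> BracketEstimate:
    """Bracket the clade's root age from the projected FADs.

    The N implied positions act as N localities of a super-lineage extending
    to the present; the oldest implied root age (or that of the named
    calibration lineage) plays the FAD role in the extant-basis confidence
    bound.  The minimum constraint is the oldest implied root age and the
    point estimate adds the average gap.
    """
    if not projections:
        raise ValueError("need at least one projected FAD")
    n = len(projections)
    oldest = max(projections, key=lambda p: p.implied_root_age)
    if calibration_lineage is None:
        chosen = oldest
    else:
        by_label = {p.lineage_id: p for p in projections}
        try:
            chosen = by_label[calibration_lineage]
        except KeyError:
            raise KeyError(
                f"no projection for lineage {calibration_lineage!r}; "
                f"have {sorted(by_label)}"
            ) from None
    result = ci_extant(chosen.implied_root_age, n, c)
    point = chosen.implied_root_age * (n + 1) / n
    return BracketEstimate(
        min_age=oldest.implied_root_age,
        soft_max_age=result.t_c,
        confidence=c,
        point_estimate=max(point, oldest.implied_root_age),
        method="supertaxon",
        notes=f"calibration lineage {chosen.lineage_id!r}, N={n}",
    )


def flag_inconsistent_fads(projections: Sequence[ProjectedFad],
                           confidence: float = 0.95) -> List[ProjectedFad]:
    """Flag projections whose implied root age is an extreme outlier.

    A projection is flagged when its implied root age exceeds the
    extant-basis confidence bound computed from the other N-1 projections
    (leave-one-out rule at ``confidence``).  Fewer than 3 projections yield
    no flags, with a warning.
    """
    n = len(projections)
    if n < 3:
        log.warning(
            "flag_inconsistent_fads: only %d projections; need >= 3 for a "
            "meaningful outlier flag", n,
        )
        return []
    flagged = []
    for i, proj in enumerate(projections):
        others = [p for j, p in enumerate(projections) if j != i]
        reference = max(p.implied_root_age for p in others)
        bound = ci_extant(reference, n - 1, confidence).t_c
        if proj.implied_root_age > bound:
            flagged.append(proj)
    return flagged
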