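"""Assembly of per-node divergence-time brackets.

Minimum constraints are apomorphy-gated: only occurrences with a documented
diagnostic character count, and the hard minimum is the *younger* dating
endpoint of the oldest such occurrence — a minimum constraint must never
overstate itself.  Soft maxima come from confidence intervals, taphonomic
control groups, or the FAD of a more inclusive clade, and can be widened by
the apomorphy-lag adjustment (divergence precedes the first fossilizable
apomorphy by up to about one species duration).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .ci import ci_for_record, unbiased_origin
from .core import AgeInterval, LineageRecord

__all__ = [
    "ControlOccurrence",
    "MinConstraint",
    "TaphonomicMax",
    "SoftMaxCandidate",
    "NodeBracket",
    "min_constraint",
    "taphonomic_max",
    "outgroup_fad_max",
    "coalescence_adjust",
    "apomorphy_lag_bound",
    "q_metric",
    "expected_fossil_species",
    "assemble_bracket",
]

log = logging.getLogger("paleobracket")


@dataclass(frozen=True)
class ControlOccurrence:
    """An occurrence of a taphonomic-control taxon (similar preservation
    potential to the focal group)."""

    control_taxon: str
    age: AgeInterval
    region: Optional[str] = None
    environment: Optional[str] = None
    horizon_id: Optional[str] = None


@dataclass(frozen=True)
class MinConstraint:
    """Hard minimum age with its dating envelope; ``valid`` is False when no
    apomorphy-documented occurrence exists."""

    valid: bool
    hard_min: Optional[float] = None
    envelope: Optional[Tuple[float, float]] = None  # (younger, older)
    source_taxon: Optional[str] = None
    reason: str = ""


def min_constraint(record: LineageRecord) -> MinConstraint:
    """Apomorphy-gated minimum constraint for a lineage.

    Uses only occurrences with ``apomorphy_documented``.  The hard minimum
    is the younger endpoint of the oldest such occurrence's age interval;
    the envelope reports both endpoints.  With no apomorphy-documented
    occurrence an explicit no-minimum result is returned.
    """
    documented = [o for o in record.occurrences if o.apomorphy_documented]
    if not documented:
        return MinConstraint(
            valid=False,
            reason="no apomorphy-documented occurrence; no valid minimum",
        )
    oldest = max(documented, key=lambda o: (o.age.older, o.age.younger))
    return MinConstraint(
        valid=True,
        hard_min=oldest.age.younger,
        envelope=(oldest.age.younger, oldest.age.older),
        source_taxon=oldest.taxon_id,
    )


@dataclass(frozen=True)
class TaphonomicMax:
    """Soft maximum from control-group occurrences older than the focal FAD.

    ``soft_max`` is the older endpoint of the *youngest* qualifying control
    horizon (the base of the first interval where controls occur without the
    focal taxon); ``conservative_max`` is the older endpoint of the *oldest*
    qualifying horizon, the bound we can be most certain of.
    """

    valid: bool
    soft_max: Optional[float] = None
    conservative_max: Optional[float] = None
    n_qualifying: int = 0
    reason: str = ""

    def __float__(self) -> float:
        if not self.valid or self.soft_max is None:
            raise ValueError(f"no taphonomic maximum: {self.reason}")
        return self.soft_max


def taphonomic_max(record: LineageRecord,
                   controls: Sequence[ControlOccurrence],
                   same_region: bool = True,
                   min_horizons: int = 1,
                   environments: Optional[Sequence[str]] = None,
                   ) -> TaphonomicMax:
    """Soft maximum from taphonomic controls preserved older than the FAD.

    A control qualifies when its age interval lies older than the focal
    FAD's older endpoint and it passes the region/environment policy.
    ``min_horizons`` requires at least that many distinct qualifying control
    horizons before a maximum is declared.
    """
    fad_older = record.fad.older
    regions = {o.region for o in record.occurrences if o.region}
    qualifying = []
    for ctl in controls:
        if ctl.age.older <= fad_older:
            continue
        if same_region and regions and ctl.region not in regions:
            continue
        if environments is not None and ctl.environment not in environments:
            continue
        qualifying.append(ctl)
    if not qualifying:
        return TaphonomicMax(valid=False,
                             reason="no qualifying control occurrence older "
                                    "than the focal FAD")
    horizons = {
        ctl.horizon_id or (ctl.age.older, ctl.age.younger, ctl.region)
        for ctl in qualifying
    }
    if len(horizons) < min_horizons:
        log.warning(
            "taphonomic_max: only %d distinct qualifying control horizons "
            "(policy requires >= %d); no maximum declared",
            len(horizons), min_horizons,
        )
        return TaphonomicMax(
            valid=False, n_qualifying=len(horizons),
            reason=f"only {len(horizons)} qualifying horizons "
                   f"(need >= {min_horizons})",
        )
    youngest = min(qualifying, key=lambda ctl: ctl.age.older)
    oldest = max(qualifying, key=lambda ctl: ctl.age.older)
    return TaphonomicMax(
        valid=True,
        soft_max=youngest.age.older,
        conservative_max=oldest.age.older,
        n_qualifying=len(horizons),
    )


def outgroup_fad_max(focal_fad: float, inclusive_clade_fad: float) -> float:
    """FAD of a more inclusive clade as an informal successive-outgroup soft
    maximum; errors when the inclusive FAD is younger than the focal one."""
    if inclusive_clade_fad < focal_fad:
        raise ValueError(
            f"inconsistent data: inclusive-clade FAD ({inclusive_clade_fad}) "
            f"is younger than the focal FAD ({focal_fad})"
        )
    if inclusive_clade_fad == focal_fad:
        log.warning(
            "outgroup_fad_max: inclusive-clade FAD equals the focal FAD; "
            "the bracket is degenerate"
        )
    return inclusive_clade_fad


def coalescence_adjust(t_dna: float, t_coalescence: float) -> float:
    """Population divergence time from a DNA-based time: T_DNA minus the
    coalescence depth contributed by ancestral polymorphism."""
    if not (0.0 <= t_coalescence <= t_dna):
        raise ValueError(
            f"need 0 <= T_coalescence <= T_DNA, got {t_coalescence} and {t_dna}"
        )
    return t_dna - t_coalescence


def apomorphy_lag_bound(soft_max_on_first_apomorphy: float,
                        mean_species_duration: float) -> float:
    """Widen a first-apomorphy soft maximum into a divergence soft maximum.

    The divergence precedes the origin of the first fossilizable apomorphy
    by at most about one average species duration, so the divergence soft
    maximum is the apomorphy soft maximum plus that duration (an upper-bound
    widening).
    """
    if mean_species_duration < 0:
        raise ValueError(
            f"species duration must be >= 0, got {mean_species_duration}"
        )
    return soft_max_on_first_apomorphy + mean_species_duration


def q_metric(extant_total: int, extant_with_fossils: int) -> float:
    """Proportion of extant taxa also found in the fossil record."""
    if extant_total < 1:
        raise ValueError(f"need extant_total >= 1, got {extant_total}")
    if not (0 <= extant_with_fossils <= extant_total):
        raise ValueError(
            f"need 0 <= extant_with_fossils <= extant_total, got "
            f"{extant_with_fossils} and {extant_total}"
        )
    return extant_with_fossils / extant_total


def expected_fossil_species(extant: float, q: float, turnover_ratio: float) -> float:
    """Expected count of preserved fossil species: extant x Q x turnover."""
    if extant < 0 or q < 0 or turnover_ratio < 0:
        raise ValueError("inputs must be nonnegative")
    return extant * q * turnover_ratio


def round_to(value: float, nearest: float) -> float:
    """Round to the nearest multiple (report policy helper)."""
    return round(value / nearest) * nearest


@dataclass(frozen=True)
class SoftMaxCandidate:
    method: str
    value: float
    notes: str = ""


@dataclass
class NodeBracket:
    """All bracket components for one node, with every adjustment logged."""

    node: str
    min: MinConstraint
    soft_max_candidates: List[SoftMaxCandidate]
    point_estimate: Optional[float]
    final_min: float
    final_max: float
    adjustments: List[str] = field(default_factory=list)
    notes: str = ""

    def to_dict(self) -> Dict:
        return {
            "node": self.node,
            "min": {
                "hard_min": self.min.hard_min,
                "envelope": self.min.envelope,
                "source_taxon": self.min.source_taxon,
            },
            "soft_max": [
                {"method": cand.method, "value": cand.value, "notes": cand.notes}
                for cand in self.soft_max_candidates
            ],
            "point_estimate": self.point_estimate,
            "adjustments": list(self.adjustments),
            "final": {"min": self.final_min, "max": self.final_max},
            "notes": self.notes,
        }


def assemble_bracket(node: str,
                     record: LineageRecord,
                     confidence: float = 0.95,
                     controls: Optional[Sequence[ControlOccurrence]] = None,
                     inclusive_clade_fad: Optional[float] = None,
                     mean_species_duration: Optional[float] = None,
                     select_method: Optional[str] = None,
                     same_region: bool = True,
                     min_horizons: int = 1,
                     endpoint: str = "mid") -> NodeBracket:
    """Assemble a node's bracket from every applicable method.

    All soft-max candidates are reported with method labels; the final
    maximum is the least restrictive candidate unless ``select_method``
    names one.  Candidates are never averaged.  Raises when the hard minimum
    exceeds the selected maximum (a data inconsistency).
    """
    minimum = min_constraint(record)
    if not minimum.valid:
        raise ValueError(f"node {node!r}: {minimum.reason}")

    adjustments: List[str] = []
    candidates: List[SoftMaxCandidate] = []

    ci = ci_for_record(record, confidence, endpoint=endpoint)
    candidates.append(SoftMaxCandidate(
        method=f"ci_{ci.basis}", value=ci.t_c,
        notes=f"C={confidence}, n={ci.n}, endpoint={endpoint}",
    ))
    point = unbiased_origin(record, endpoint=endpoint)

    if controls:
        taph = taphonomic_max(record, controls, same_region=same_region,
                              min_horizons=min_horizons)
        if taph.valid:
            candidates.append(SoftMaxCandidate(
                method="taphonomic_control", value=taph.soft_max,
                notes=f"conservative_max={taph.conservative_max}, "
                      f"n_qualifying={taph.n_qualifying}",
            ))

    if inclusive_clade_fad is not None:
        value = outgroup_fad_max(record.fad_value(endpoint), inclusive_clade_fad)
        candidates.append(SoftMaxCandidate(
            method="outgroup_fad", value=value,
            notes="informal successive-outgroup rule",
        ))

    if mean_species_duration is not None:
        widened = []
        for cand in candidates:
            value = apomorphy_lag_bound(cand.value, mean_species_duration)
            widened.append(SoftMaxCandidate(
                method=cand.method, value=value,
                notes=(cand.notes + "; " if cand.notes else "")
                      + f"apomorphy lag +{mean_species_duration} Myr",
            ))
        adjustments.append(
            f"apomorphy lag bound: soft maxima widened by "
            f"{mean_species_duration} Myr (upper-bound widening)"
        )
        candidates = widened

    if select_method is not None:
        matching = [c for c in candidates if c.method == select_method]
        if not matching:
            raise ValueError(
                f"no soft-max candidate with method {select_method!r}; "
                f"have {[c.method for c in candidates]}"
            )
        final_max = max(c.value for c in matching)
        adjustments.append(f"final maximum selected by method {select_method!r}")
    else:
        final_max = max(c.value for c in candidates)
        adjustments.append("final maximum = least restrictive candidate")

    if minimum.hard_min > final_max:
        raise ValueError(
            f"node {node!r}: hard minimum {minimum.hard_min} exceeds selected "
            f"maximum {final_max} (data inconsistency)"
        )

    return NodeBracket(
        node=node,
        min=minimum,
        soft_max_candidates=candidates,
        point_estimate=point,
        final_min=minimum.hard_min,
        final_max=final_max,
        adjustments=adjustments,
    )
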