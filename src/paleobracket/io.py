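"""Readers and writers for occurrence tables, recovery curves and trees.

Occurrence tables are CSV (comma default, tab accepted) with named columns:

    taxon_id, lineage_id, locality_id, horizon_id, age_older_ma,
    age_younger_ma, region, axis_position, apomorphy, voucher

``taxon_id``, ``lineage_id``, ``locality_id``, ``age_older_ma`` and
``age_younger_ma`` are required; the rest are optional.  Floats are written
with ``repr`` so a write/read round trip is bit-exact.
"""

from __future__ import annotations

import csv
import logging
from typing import Dict, Iterable, List, Mapping, Optional, Union

from .core import (
    AgeInterval,
    FossilOccurrence,
    LineageRecord,
    RecoveryCurve,
    UltrametricTopology,
)

log = logging.getLogger("paleobracket")

REQUIRED_COLUMNS = (
    "taxon_id", "lineage_id", "locality_id", "age_older_ma", "age_younger_ma",
)
OPTIONAL_COLUMNS = ("horizon_id", "region", "axis_position", "apomorphy", "voucher")
ALL_COLUMNS = REQUIRED_COLUMNS[:3] + ("horizon_id",) + REQUIRED_COLUMNS[3:] + (
    "region", "axis_position", "apomorphy", "voucher",
)

_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n", ""}


def _parse_bool(value: str, row_num: int) -> bool:
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValueError(f"row {row_num}: cannot parse apomorphy flag {value!r}")


def _sniff_delimiter(path: str, dialect: Optional[str]) -> str:
    if dialect in (",", "\t"):
        return dialect
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    with open(path, newline="") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_occurrences(path: str, dialect: Optional[str] = None) -> List[FossilOccurrence]:
    """Read an occurrence table, validating rows as they are parsed.

    Raises ``ValueError`` naming the column if a required column is absent,
    or citing the (1-based, header-exclusive) row number on a bad row.
    """
    delimiter = _sniff_delimiter(path, dialect)
    occurrences: List[FossilOccurrence] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, header row required")
        fields = [f.strip() for f in reader.fieldnames]
        for col in REQUIRED_COLUMNS:
            if col not in fields:
                raise ValueError(f"{path}: missing required column {col!r}")
        for row_num, row in enumerate(reader, start=1):
            row = {(k.strip() if k else k): v for k, v in row.items()}
            try:
                older = float(row["age_older_ma"])
                younger = float(row["age_younger_ma"])
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path} row {row_num}: bad age value ({exc})")
            if younger > older:
                raise ValueError(
                    f"{path} row {row_num}: age_younger_ma ({younger}) exceeds "
                    f"age_older_ma ({older})"
                )
            axis_raw = (row.get("axis_position") or "").strip()
            occurrences.append(FossilOccurrence(
                taxon_id=row["taxon_id"],
                lineage_id=row["lineage_id"],
                locality_id=row["locality_id"],
                horizon_id=(row.get("horizon_id") or "").strip() or None,
                age=AgeInterval(older=older, younger=younger),
                region=(row.get("region") or "").strip() or None,
                axis_position=float(axis_raw) if axis_raw else None,
                apomorphy_documented=_parse_bool(row.get("apomorphy") or "", row_num),
                voucher=(row.get("voucher") or "").strip() or None,
            ))
    log.info("read %d occurrences from %s", len(occurrences), path)
    return occurrences


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def write_occurrences(occurrences: Iterable[FossilOccurrence], path: str,
                      delimiter: str = ",") -> None:
    """Write an occurrence table that round-trips bit-exactly through
    :func:`read_occurrences`."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(ALL_COLUMNS)
        for occ in occurrences:
            writer.writerow([
                _fmt(occ.taxon_id), _fmt(occ.lineage_id), _fmt(occ.locality_id),
                _fmt(occ.horizon_id), _fmt(occ.age.older), _fmt(occ.age.younger),
                _fmt(occ.region), _fmt(occ.axis_position),
                _fmt(occ.apomorphy_documented), _fmt(occ.voucher),
            ])


def group_records(occurrences: Iterable[FossilOccurrence],
                  extant: Union[bool, Mapping[str, bool]] = False,
                  ) -> Dict[str, LineageRecord]:
    """Group occurrences into per-lineage records, keyed and sorted by lineage id.

    ``extant`` is either a single flag for all lineages or a mapping from
    lineage id to flag (missing entries default to extinct).
    """
    by_lineage: Dict[str, list] = {}
    for occ in occurrences:
        by_lineage.setdefault(occ.lineage_id, []).append(occ)

    def flag(lineage_id: str) -> bool:
        if isinstance(extant, Mapping):
            return bool(extant.get(lineage_id, False))
        return bool(extant)

    return {
        lid: LineageRecord(lid, flag(lid), occs)
        for lid, occs in sorted(by_lineage.items())
    }


def read_newick(path: str, tol: float = 1e-9) -> UltrametricTopology:
    """Read a single rooted ultrametric newick tree with branch lengths,
    normalizing depths so the root is at relative depth 1."""
    return UltrametricTopology.from_newick(path, tol=tol)


def read_recovery_curve(path: str, dialect: Optional[str] = None) -> RecoveryCurve:
    """Read a piecewise-constant recovery curve.

    Columns: ``age_older_ma``, ``age_younger_ma``, ``relative_rate``.  The
    intervals must tile ``[0, t_max]`` contiguously (youngest interval must
    start at age 0).
    """
    delimiter = _sniff_delimiter(path, dialect)
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, header row required")
        for col in ("age_older_ma", "age_younger_ma", "relative_rate"):
            if col not in [f.strip() for f in reader.fieldnames]:
                raise ValueError(f"{path}: missing required column {col!r}")
        for row_num, row in enumerate(reader, start=1):
            rows.append((
                float(row["age_younger_ma"]),
                float(row["age_older_ma"]),
                float(row["relative_rate"]),
            ))
    if not rows:
        raise ValueError(f"{path}: recovery curve has no intervals")
    rows.sort()
    breakpoints = [rows[0][0]]
    rates = []
    for younger, older, rate in rows:
        if abs(younger - breakpoints[-1]) > 1e-12:
            raise ValueError(
                f"{path}: recovery-curve intervals must tile contiguously; "
                f"gap or overlap at age {younger}"
            )
        breakpoints.append(older)
        rates.append(rate)
    return RecoveryCurve(breakpoints, rates)
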