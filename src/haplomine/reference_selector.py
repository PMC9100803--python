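"""Reference sub-panel selection.

Chooses, within every geographic-region x variety-group cell of a phenotyped
pool, the accessions with the maximal and minimal phenotype, and unions them
with an always-kept core list. This maximises phenotypic extremes (and hence
the chance of extreme-associated haplotypes) while keeping the reference
panel small.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import AccessionRecord


@dataclass(frozen=True)
class SelectionCell:
    region: str
    variety_group: str
    members: tuple[tuple[str, float], ...]


def _cells(records: Iterable[AccessionRecord]) -> dict[tuple[str, str], list]:
    cells: dict[tuple[str, str], list] = {}
    for rec in records:
        if rec.phenotype is None:
            warnings.warn(f"accession {rec.accession_id} has no phenotype; skipped")
            continue
        key = (rec.region or "unknown", rec.variety_group or "unknown")
        cells.setdefault(key, []).append((rec.accession_id, rec.phenotype))
    return cells


def _extreme(members: list[tuple[str, float]], sign: int) -> str:
    # ties broken by lexicographically smallest accession id
    return min(members, key=lambda m: (sign * m[1], m[0]))[0]


def select_extremes(
    records: Iterable[AccessionRecord],
    core_list: Sequence[str] = (),
) -> list[str]:
    """Selected accession ids: per-cell argmax/argmin plus the core list.

    Deterministic: ties go to the lexicographically smallest accession id,
    and the result is sorted by accession id.
    """
    cells = _cells(records)
    if not cells and not core_list:
        warnings.warn("no phenotyped accessions to select from")
        return []
    selected: set[str] = set(core_list)
    for members in cells.values():
        selected.add(_extreme(members, -1))  # max
        selected.add(_extreme(members, +1))  # min
    return sorted(selected)


def selection_table(
    records: Iterable[AccessionRecord],
    core_list: Sequence[str] = (),
) -> pd.DataFrame:
    """Long-form report of selection events (one row per accession x rank)."""
    cells = _cells(records)
    rows = []
    for (region, group), members in sorted(cells.items()):
        rows.append({
            "accession_id": _extreme(members, -1), "region": region,
            "variety_group": group, "rank": "max",
        })
        rows.append({
            "accession_id": _extreme(members, +1), "region": region,
            "variety_group": group, "rank": "min",
        })
    for acc in core_list:
        rows.append({
            "accession_id": acc, "region": "", "variety_group": "", "rank": "core",
        })
    frame = pd.DataFrame(rows, columns=["accession_id", "region", "variety_group", "rank"])
    return frame.sort_values(["accession_id", "rank"], kind="mergesort").reset_index(drop=True)
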