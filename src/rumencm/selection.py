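"""Group- and genus-level selection summaries from NCM partition tables.

Aggregates the above / neutral / below labels of per-timepoint partition
tables into proportions and cross-timepoint min–max ranges, at the whole
group level or within named genera (matched on the GTDB genus rank).  Range
strings use one decimal, e.g. ``"20.4%–28.2%"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .ncm import PARTITION_LABELS
from .study_io import TaxonomyTable

__all__ = ["SelectionSummary", "partition_proportions", "taxon_selection_ranges"]


@dataclass
class SelectionSummary:
    """Per-timepoint partition proportions plus cross-timepoint ranges.

    ``proportions``: rows (name, timepoint), columns n_sgb, prop_above,
    prop_neutral, prop_below.  ``ranges``: rows name, columns
    above/neutral/below range strings plus the timepoints covered.
    """

    unit: str  # "group" or "genus"
    proportions: pd.DataFrame
    ranges: pd.DataFrame


def _proportions_row(table: pd.DataFrame) -> dict[str, float]:
    n = len(table)
    row: dict[str, float] = {"n_sgb": n}
    for lab in PARTITION_LABELS:
        row[f"prop_{lab}"] = float((table["label"] == lab).mean()) if n else float("nan")
    return row


def format_range(values: list[float]) -> str:
    """Min–max percentage range with one decimal, as reported in results text."""
    lo, hi = min(values), max(values)
    return f"{100 * lo:.1f}%–{100 * hi:.1f}%"


def partition_proportions(
    tables: dict[str, pd.DataFrame], name: str = "all"
) -> SelectionSummary:
    """Group-level proportions per timepoint and min–max ranges across them.

    ``tables`` maps timepoint -> partition table (output of
    ``classify_partitions``).  Denominators are the fitted SGBs of each
    timepoint (undetected SGBs never enter partition tables).
    """
    if not tables:
        raise ValueError("need >=1 partition table")
    rows = []
    for tp, table in tables.items():
        if len(table) == 0:
            raise ValueError(f"empty partition table at timepoint {tp}")
        rows.append({"name": name, "timepoint": tp, **_proportions_row(table)})
    props = pd.DataFrame(rows)
    ranges = pd.DataFrame([{
        "name": name,
        "timepoints": ",".join(tables),
        **{f"range_{lab}": format_range(list(props[f"prop_{lab}"]))
           for lab in PARTITION_LABELS},
    }])
    return SelectionSummary("group", props, ranges)


def taxon_selection_ranges(
    tables: dict[str, pd.DataFrame],
    tax: TaxonomyTable,
    genera: list[str],
) -> SelectionSummary:
    """Per-genus selection proportions and cross-timepoint ranges.

    The denominator at each timepoint is the number of fitted SGBs of that
    genus at that timepoint.  A genus with zero fitted SGBs at a timepoint is
    absent there (no row), not zero; its range covers the timepoints where it
    is present, and ``present_at`` records which.  A genus matching no SGB in
    any table is dropped with a warning row in neither output.
    """
    if not tables:
        raise ValueError("need >=1 partition table")
    prop_rows = []
    range_rows = []
    all_tps = list(tables)
    for genus in genera:
        members = set(tax.sgbs_in_genus(genus))
        per_tp: dict[str, dict[str, float]] = {}
        for tp, table in tables.items():
            sub = table[table["sgb_id"].isin(members)]
            if len(sub) == 0:
                continue
            per_tp[tp] = _proportions_row(sub)
            prop_rows.append({"name": genus, "timepoint": tp, **per_tp[tp]})
        if not per_tp:
            import warnings
            warnings.warn(f"genus {genus!r} matches no fitted SGB in any table; omitted")
            continue
        range_rows.append({
            "name": genus,
            "timepoints": ",".join(per_tp),
            "present_at": len(per_tp),
            "partial": len(per_tp) < len(all_tps),
            **{f"range_{lab}": format_range([r[f"prop_{lab}"] for r in per_tp.values()])
               for lab in PARTITION_LABELS},
        })
    return SelectionSummary(
        "genus",
        pd.DataFrame(prop_rows,
                     columns=["name", "timepoint", "n_sgb",
                              "prop_above", "prop_neutral", "prop_below"]),
        pd.DataFrame(range_rows),
    )
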