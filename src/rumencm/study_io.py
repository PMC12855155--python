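"""Data model and I/O for SGB count matrices, sample metadata and taxonomy.

The unit of analysis is the SGB (species-level genome bin): a dereplicated
genome cluster at ~95% ANI standing in for a microbial species.  Count
matrices hold raw mapped-read counts of each SGB in each sample (one rumen
fluid sample per animal per time point).  Metadata assigns each sample to an
animal, a diet arm (forage F / grain G), a feed-efficiency group (HFE / LFE)
and one of four sampling days.  Slicing by (feed-efficiency group, time
point) yields the per-slice matrices on which the neutral community model is
fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DIETS = ("F", "G")
FE_GROUPS = ("HFE", "LFE")
TIMEPOINTS = ("D1", "D80", "D100", "D180")

#: accepted spellings for timepoint tokens, normalized to D<day>
_TIMEPOINT_ALIASES = {
    "D1": "D1", "DAY1": "D1", "DAY 1": "D1", "1": "D1",
    "D80": "D80", "DAY80": "D80", "DAY 80": "D80", "80": "D80",
    "D100": "D100", "DAY100": "D100", "DAY 100": "D100", "100": "D100",
    "D180": "D180", "DAY180": "D180", "DAY 180": "D180", "180": "D180",
}


class FormatError(ValueError):
    """Malformed input file (non-integer cell, bad header, ...)."""


class ValidationError(ValueError):
    """Structurally valid file that violates a contract (duplicates, bad levels)."""


class EmptySliceError(ValueError):
    """A slice specification matched no samples."""


class InsufficientReplicationError(ValueError):
    """A slice resolved to fewer samples than the analysis requires."""


def normalize_timepoint(token: str) -> str:
    key = str(token).strip().upper()
    if key in _TIMEPOINT_ALIASES:
        return _TIMEPOINT_ALIASES[key]
    raise ValidationError(
        f"unknown timepoint {token!r}; expected one of {TIMEPOINTS} "
        "(or 'Day 1' style aliases)"
    )


@dataclass
class CountMatrix:
    """Integer read counts, SGBs as rows and samples as columns."""

    sgb_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_sgb, n_sample) integer

    def __post_init__(self) -> None:
        self.sgb_ids = [str(s) for s in self.sgb_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValidationError("counts must be integer-valued")
            counts = counts.astype(np.int64)
        self.counts = np.ascontiguousarray(counts, dtype=np.int64)
        if self.counts.shape != (len(self.sgb_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sgb_ids)} SGBs x {len(self.sample_ids)} samples"
            )
        if self.counts.size and self.counts.min() < 0:
            raise ValidationError("counts must be non-negative")
        for label, ids in (("SGB", self.sgb_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if ids.count(x) > 1})
                raise ValidationError(f"duplicate {label} identifiers: {dupes}")

    @property
    def n_sgb(self) -> int:
        return len(self.sgb_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sgb_ids, columns=self.sample_ids)

    def select_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(list(self.sgb_ids), list(sample_ids), self.counts[:, idx])


@dataclass
class SampleMetadata:
    """Per-sample design table: animal, diet, feed-efficiency group, time point."""

    table: pd.DataFrame  # index sample_id; columns animal_id, diet, fe_group, timepoint

    def __post_init__(self) -> None:
        required = ["animal_id", "diet", "fe_group", "timepoint"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"metadata missing columns {missing}")
        if self.table.index.has_duplicates:
            dupes = sorted(self.table.index[self.table.index.duplicated()].unique())
            raise ValidationError(f"duplicate sample_id values: {dupes}")
        tbl = self.table.copy()
        tbl["timepoint"] = [normalize_timepoint(t) for t in tbl["timepoint"]]
        for col, levels in (("diet", DIETS), ("fe_group", FE_GROUPS)):
            bad = sorted(set(tbl[col]) - set(levels))
            if bad:
                raise ValidationError(f"unknown {col} level(s) {bad}; expected {levels}")
        pairs = tbl[["animal_id", "timepoint"]]
        if pairs.duplicated().any():
            raise ValidationError("duplicate (animal_id, timepoint) pairs in metadata")
        self.table = tbl

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_for(self, fe_group: str, timepoint: str,
                    diet: str | None = None) -> list[str]:
        tbl = self.table
        mask = (tbl["fe_group"] == fe_group) & (tbl["timepoint"] == normalize_timepoint(timepoint))
        if diet is not None:
            mask &= tbl["diet"] == diet
        return list(tbl.index[mask])


@dataclass
class TaxonomyTable:
    """SGB -> GTDB-style lineage, with the genus token pre-extracted.

    Lineages are semicolon-separated 7-rank strings
    (``d__...;p__...;c__...;o__...;f__...;g__...;s__...``); trailing ranks may
    be absent.  Genus matching elsewhere strips the ``g__`` prefix.
    """

    lineages: dict[str, str]
    genus: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        self.genus = {}
        for sgb, lineage in self.lineages.items():
            ranks = [r.strip() for r in str(lineage).split(";")]
            if len(ranks) > 7:
                raise ValidationError(
                    f"lineage for {sgb!r} has {len(ranks)} ranks (max 7): {lineage!r}"
                )
            g = ""
            for r in ranks:
                if r.startswith("g__"):
                    g = r[3:]
            self.genus[sgb] = g

    def sgbs_in_genus(self, genus: str) -> list[str]:
        name = genus[3:] if genus.startswith("g__") else genus
        return [s for s, g in self.genus.items() if g == name]


@dataclass(frozen=True)
class SliceSpec:
    """One (feed-efficiency group, time point) cell of the design, optionally
    restricted to a single diet arm."""

    fe_group: str
    timepoint: str
    diet: str | None = None

    def __post_init__(self) -> None:
        if self.fe_group not in FE_GROUPS:
            raise ValidationError(f"fe_group must be one of {FE_GROUPS}")
        object.__setattr__(self, "timepoint", normalize_timepoint(self.timepoint))
        if self.diet is not None and self.diet not in DIETS:
            raise ValidationError(f"diet must be one of {DIETS}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a tab-delimited SGB x sample count table.

    First column holds SGB identifiers (header cell ignored), remaining
    header cells are sample identifiers, body cells are non-negative
    integers.  Malformed cells raise :class:`FormatError` naming the
    offending row and column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    sgb_ids = [str(i) for i in df.index]
    sample_ids = [str(c) for c in df.columns]
    counts = np.zeros((len(sgb_ids), len(sample_ids)), dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                value = int(str(raw))
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path.name}: non-integer cell {raw!r} at "
                    f"(row {i + 1}, col {j + 1}) [SGB {sgb_ids[i]!r}, sample {sample_ids[j]!r}]"
                ) from None
            if value < 0:
                raise FormatError(
                    f"{path.name}: negative count {value} at "
                    f"(row {i + 1}, col {j + 1})"
                )
            counts[i, j] = value
    return CountMatrix(sgb_ids, sample_ids, counts)


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    df = cm.to_frame()
    df.index.name = "sgb_id"
    df.to_csv(path, sep="\t")


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    """Read a CSV with columns sample_id, animal_id, diet, fe_group, timepoint."""
    df = pd.read_csv(path, dtype=str)
    required = ["sample_id", "animal_id", "diet", "fe_group", "timepoint"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{Path(path).name}: missing metadata column(s) {missing}")
    df = df.set_index("sample_id")
    return SampleMetadata(df[["animal_id", "diet", "fe_group", "timepoint"]])


def write_sample_metadata(md: SampleMetadata, path: str | Path) -> None:
    out = md.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path)


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a two-column TSV: sgb_id, GTDB lineage string."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{Path(path).name}: taxonomy needs >=2 columns (sgb_id, lineage)")
    sgb_col, lin_col = df.columns[0], df.columns[1]
    if df[sgb_col].duplicated().any():
        raise ValidationError("duplicate sgb_id in taxonomy table")
    return TaxonomyTable(dict(zip(df[sgb_col], df[lin_col].fillna(""))))


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    pd.DataFrame(
        {"sgb_id": list(tax.lineages), "lineage": list(tax.lineages.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# slicing
# ---------------------------------------------------------------------------

def slice_group_timepoint(cm: CountMatrix, md: SampleMetadata,
                          spec: SliceSpec) -> CountMatrix:
    """Column-subset a count matrix to one (fe_group, timepoint) design cell.

    All SGB rows are retained, even if all-zero within the slice; dropping
    undetected SGBs is an analysis decision made at model-fitting time, so
    slicing stays non-destructive.
    """
    samples = [s for s in md.samples_for(spec.fe_group, spec.timepoint, spec.diet)
               if s in set(cm.sample_ids)]
    if not samples:
        raise EmptySliceError(f"no samples match {spec}")
    if len(samples) < 2:
        raise InsufficientReplicationError(
            f"{spec} matched only {len(samples)} sample(s); >=2 required"
        )
    animals = set(md.table.loc[samples, "animal_id"])
    if len(animals) < 2:
        raise InsufficientReplicationError(
            f"{spec} resolves to samples from a single animal"
        )
    return cm.select_samples(samples)


def canonical_slices(md: SampleMetadata) -> list[SliceSpec]:
    """The 8 (fe_group x timepoint) cells present in the metadata."""
    cells = []
    for fe in FE_GROUPS:
        for tp in TIMEPOINTS:
            if md.samples_for(fe, tp):
                cells.append(SliceSpec(fe, tp))
    return cells
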