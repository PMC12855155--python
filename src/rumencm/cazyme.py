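"""CAZyme domain-architecture parsing and CBM tandem-structure profiling.

Carbohydrate-binding modules (CBMs) are non-catalytic domains that adhere
carbohydrate-active enzymes to their polysaccharide substrates; consecutive
("tandem") CBMs on one protein amplify binding avidity.  This module parses
dbCAN-style architecture strings such as ``CBM11+CBM11+CBM11+GH51`` into
ordered domain tokens, detects maximal tandem CBM runs, and counts per
genome the CBM-associated catalytic enzyme structures: proteins carrying at
least one CBM and at least one catalytic domain (GH, PL, CE or AA class).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DomainArchitecture",
    "GenomeCBMProfile",
    "parse_architecture",
    "detect_tandem_cbms",
    "count_cbm_structures",
    "genome_cbm_ranking",
    "read_architecture_table",
    "profile_genomes",
]

DEFAULT_DELIMITERS = frozenset({"+", "|", "-"})
#: catalytic CAZyme classes; GT excluded by default (not substrate-degrading)
DEFAULT_CATALYTIC_CLASSES = ("GH", "PL", "CE", "AA")
#: a complete domain token: class letters + family number + optional subfamily
_TOKEN_RE = re.compile(r"^[A-Za-z]+\d+(?:_\d+)?$")


class ParseError(ValueError):
    """Architecture string yielded no tokens."""


@dataclass
class DomainArchitecture:
    """Ordered domain tokens of one protein, with per-token classes."""

    protein_id: str
    genome_id: str
    tokens: list[str]
    classes: list[str] = field(default_factory=list)  # "CBM" | "catalytic" | "other"

    @property
    def has_cbm(self) -> bool:
        return "CBM" in self.classes

    @property
    def has_catalytic(self) -> bool:
        return "catalytic" in self.classes


@dataclass
class GenomeCBMProfile:
    """Per-genome CBM-structure counts and tandem-run statistics."""

    genome_id: str
    n_proteins: int
    n_cbm_structures: int
    n_adjacency_pairs: int
    max_tandem_run: int
    tandem_run_histogram: dict[int, int]
    cbm_families: set[str]
    catalytic_families: set[str]


def classify_token(token: str,
                   catalytic_classes: tuple[str, ...] = DEFAULT_CATALYTIC_CLASSES
                   ) -> str:
    if token.upper().startswith("CBM"):
        return "CBM"
    for cls in catalytic_classes:
        if token.upper().startswith(cls) and _TOKEN_RE.match(token):
            return "catalytic"
    return "other"


def family_of(token: str) -> str:
    """Family label: the token with any _subfamily suffix stripped (GH43_16 -> GH43)."""
    return token.split("_", 1)[0]


def parse_architecture(
    raw: str,
    protein_id: str = "",
    genome_id: str = "",
    delimiters: frozenset[str] = DEFAULT_DELIMITERS,
    catalytic_classes: tuple[str, ...] = DEFAULT_CATALYTIC_CLASSES,
) -> DomainArchitecture:
    """Split an architecture string into ordered, classified domain tokens.

    Splits on ``+`` and ``|`` freely.  ``-`` is ambiguous (it appears inside
    some annotation labels), so a piece is split on hyphens only when every
    resulting fragment looks like a complete domain token (letters + family
    number, optional ``_subfamily``); otherwise the piece is kept whole.
    """
    if raw is None or not str(raw).strip():
        raise ParseError(f"empty architecture string for protein {protein_id!r}")
    text = str(raw).strip()
    hard = [dlm for dlm in delimiters if dlm != "-"]
    pieces = [text]
    for dlm in hard:
        pieces = [frag for piece in pieces for frag in piece.split(dlm)]
    tokens: list[str] = []
    for piece in pieces:
        piece = piece.strip()
        if not piece:
            continue
        if "-" in piece and "-" in delimiters:
            frags = [f.strip() for f in piece.split("-")]
            if all(_TOKEN_RE.match(f) for f in frags if f):
                tokens.extend(f for f in frags if f)
                continue
        tokens.append(piece)
    if not tokens:
        raise ParseError(f"no domain tokens in architecture {raw!r}")
    classes = [classify_token(t, catalytic_classes) for t in tokens]
    return DomainArchitecture(protein_id, genome_id, tokens, classes)


def detect_tandem_cbms(arch: DomainArchitecture, min_run: int = 2
                       ) -> list[tuple[int, int]]:
    """Maximal runs of consecutive CBM tokens of length >= ``min_run``.

    Returns ``(start_index, run_length)`` pairs, 0-based, left to right.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    runs: list[tuple[int, int]] = []
    i, n = 0, len(arch.classes)
    while i < n:
        if arch.classes[i] == "CBM":
            j = i
            while j < n and arch.classes[j] == "CBM":
                j += 1
            if j - i >= min_run:
                runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def count_cbm_structures(archs: list[DomainArchitecture]) -> GenomeCBMProfile:
    """Profile one genome's CBM-associated catalytic enzyme structures.

    A structure is a protein with >=1 CBM and >=1 catalytic domain, counted
    once per protein regardless of token order or multiplicity.  An
    alternative adjacency-pair count (CBM token directly next to a catalytic
    token, summed over positions) is reported alongside.
    """
    genomes = {a.genome_id for a in archs}
    if len(genomes) > 1:
        raise ValueError(f"mixed genome_ids in one profile: {sorted(genomes)}")
    genome_id = archs[0].genome_id if archs else ""
    n_struct = 0
    n_adj = 0
    hist: dict[int, int] = {}
    max_run = 0
    cbm_fams: set[str] = set()
    cat_fams: set[str] = set()
    for arch in archs:
        if not (arch.has_cbm and arch.has_catalytic):
            continue
        n_struct += 1
        cbm_fams.update(family_of(t) for t, c in zip(arch.tokens, arch.classes)
                        if c == "CBM")
        cat_fams.update(family_of(t) for t, c in zip(arch.tokens, arch.classes)
                        if c == "catalytic")
        for (start, length) in detect_tandem_cbms(arch, min_run=1):
            hist[length] = hist.get(length, 0) + 1
            max_run = max(max_run, length)
        for a, b in zip(arch.classes, arch.classes[1:]):
            if {a, b} == {"CBM", "catalytic"}:
                n_adj += 1
    return GenomeCBMProfile(
        genome_id=genome_id,
        n_proteins=len(archs),
        n_cbm_structures=n_struct,
        n_adjacency_pairs=n_adj,
        max_tandem_run=max_run,
        tandem_run_histogram=hist,
        cbm_families=cbm_fams,
        catalytic_families=cat_fams,
    )


def read_architecture_table(path) -> list[DomainArchitecture]:
    """Read a TSV with columns protein_id, genome_id, architecture."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["protein_id", "genome_id", "architecture"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"architecture table missing column(s) {missing}")
    return [parse_architecture(r.architecture, r.protein_id, r.genome_id)
            for r in df.itertuples()]


def profile_genomes(archs: list[DomainArchitecture]) -> list[GenomeCBMProfile]:
    by_genome: dict[str, list[DomainArchitecture]] = {}
    for a in archs:
        by_genome.setdefault(a.genome_id, []).append(a)
    return [count_cbm_structures(v) for _, v in sorted(by_genome.items())]


def genome_cbm_ranking(
    profiles: list[GenomeCBMProfile],
    groups: dict[str, str],
    count_field: str = "n_cbm_structures",
) -> pd.DataFrame:
    """Compare CBM-structure counts between genome groups.

    Returns one row per group with median and IQR of the per-genome count,
    plus (two-group case) the fold-difference of medians and a Mann–Whitney
    U p-value.  Groups mapping to zero genomes are omitted with a warning.
    """
    by_group: dict[str, list[float]] = {}
    for prof in profiles:
        g = groups.get(prof.genome_id)
        if g is not None:
            by_group.setdefault(g, []).append(float(getattr(prof, count_field)))
    declared = sorted(set(groups.values()))
    for g in declared:
        if g not in by_group:
            import warnings
            warnings.warn(f"group {g!r} has no genomes; omitted from ranking")
    names = sorted(by_group)
    if len(names) < 2:
        raise ValueError("need >=2 non-empty groups to rank")
    rows = []
    for g in names:
        vals = np.asarray(by_group[g])
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append({"group": g, "n_genomes": vals.size, "median": med,
                     "iqr_low": q1, "iqr_high": q3})
    out = pd.DataFrame(rows)
    if len(names) == 2:
        m0, m1 = out["median"].iloc[0], out["median"].iloc[1]
        hi, lo = max(m0, m1), min(m0, m1)
        out["fold_difference"] = hi / lo if lo > 0 else np.inf
        u = stats.mannwhitneyu(by_group[names[0]], by_group[names[1]],
                               alternative="two-sided")
        out["mannwhitney_p"] = u.pvalue
    return out
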