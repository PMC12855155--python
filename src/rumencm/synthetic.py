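"""Synthetic study generator with the statistical structure the analysis assumes.

Generates SGB read-count matrices for a two-group (HFE/LFE), four-timepoint
repeated-measures bull study: a long-tailed (lognormal) metacommunity, local
relative abundances drawn per animal from the neutral stationary Beta law
``Beta(Nm*p_i, Nm*(1-p_i))``, Poisson library sizes, multinomial read
sampling, and optional injection of positively / negatively selected taxa
that break the neutral occupancy pattern.  Also generates CAZyme
domain-architecture tables with controllable tandem-CBM enrichment.

All randomness flows through one ``numpy.random.Generator`` seeded per call;
identical parameters and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .study_io import CountMatrix, SampleMetadata, TaxonomyTable, TIMEPOINTS

__all__ = [
    "SimTruth",
    "StudyDesign",
    "simulate_neutral_slice",
    "inject_selection",
    "simulate_study",
    "simulate_domain_annotations",
]


@dataclass
class SimTruth:
    """Ground truth for one simulated slice."""

    Nm_true: float
    p_meta: np.ndarray
    selected_above: set[str] = field(default_factory=set)
    selected_below: set[str] = field(default_factory=set)
    depth_mean: float = 1e5
    seed: int = 0

    def __post_init__(self) -> None:
        self.p_meta = np.asarray(self.p_meta, dtype=float)
        if self.p_meta.size and (self.p_meta.min() <= 0
                                 or abs(self.p_meta.sum() - 1.0) > 1e-12):
            raise ValueError("p_meta entries must be > 0 and sum to 1")
        if self.selected_above & self.selected_below:
            raise ValueError("selected_above and selected_below must be disjoint")


def simulate_neutral_slice(
    n_sgb: int,
    n_animals: int,
    Nm_true: float,
    depth_mean: float = 1e5,
    abundance_shape: float = 2.0,
    seed: int = 0,
    sgb_prefix: str = "SGB",
    sample_prefix: str = "S",
) -> tuple[CountMatrix, SimTruth]:
    """One neutral group-timepoint slice.

    Metacommunity abundances are lognormal(0, ``abundance_shape``) normalized
    to sum 1 (a long right tail, as in real SGB profiles); each animal's
    local relative abundance of SGB i is an independent
    ``Beta(Nm_true*p_i, Nm_true*(1-p_i))`` draw, renormalized within the
    animal; library size is Poisson(``depth_mean``) and reads are multinomial.
    """
    if n_sgb < 1:
        raise ValueError("n_sgb must be >= 1")
    if n_animals < 2:
        raise ValueError("n_animals must be >= 2")
    if Nm_true <= 0:
        raise ValueError("Nm_true must be positive")
    rng = np.random.default_rng(seed)
    if n_sgb == 1:
        p = np.array([1.0])
        depths = rng.poisson(depth_mean, size=n_animals)
        counts = depths[np.newaxis, :].astype(np.int64)
    else:
        raw = rng.lognormal(mean=0.0, sigma=abundance_shape, size=n_sgb)
        p = raw / raw.sum()
        alpha = Nm_true * p
        beta = Nm_true * (1.0 - p)
        if alpha.min() <= 0 or not np.all(np.isfinite(alpha)):
            raise ValueError(
                "Nm_true * p_i underflowed to 0; use a larger Nm_true or fewer SGBs"
            )
        local = rng.beta(alpha[:, None], beta[:, None], size=(n_sgb, n_animals))
        # Beta draws can underflow to exactly 0 for tiny alpha; harmless (absent taxon)
        local /= local.sum(axis=0, keepdims=True)
        depths = rng.poisson(depth_mean, size=n_animals)
        counts = np.empty((n_sgb, n_animals), dtype=np.int64)
        for j in range(n_animals):
            counts[:, j] = rng.multinomial(depths[j], local[:, j])
    cm = CountMatrix(
        [f"{sgb_prefix}{i:05d}" for i in range(n_sgb)],
        [f"{sample_prefix}{j:02d}" for j in range(n_animals)],
        counts,
    )
    truth = SimTruth(Nm_true=float(Nm_true), p_meta=p,
                     depth_mean=float(depth_mean), seed=seed)
    return cm, truth


def _eligible_terciles(p_meta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the bottom abundance tercile and of the mid/high terciles."""
    order = np.argsort(p_meta, kind="stable")
    cut = len(order) // 3
    return order[:cut], order[cut:]


#: total metacommunity share that zeroing below-taxa may remove per sample;
#: half the 1% depth-perturbation budget, leaving headroom for Beta noise
_BELOW_ABUNDANCE_BUDGET = 0.005


def _eligible_below(p_meta: np.ndarray, n_below: int) -> np.ndarray:
    """Mid/high-tercile candidates for negative selection whose combined
    abundance keeps column-depth changes within the perturbation budget."""
    _, midhigh = _eligible_terciles(p_meta)
    if n_below == 0:
        return midhigh
    cap = _BELOW_ABUNDANCE_BUDGET / n_below
    return midhigh[p_meta[midhigh] <= cap]


def inject_selection(
    cm: CountMatrix,
    truth: SimTruth,
    n_above: int,
    n_below: int,
    seed: int = 0,
) -> tuple[CountMatrix, SimTruth]:
    """Overwrite the occupancy pattern of chosen taxa to mimic selection.

    Positively selected taxa are drawn from the bottom abundance tercile
    (where neutral occupancy is low) and forced present (count >= 1) in every
    animal; negatively selected taxa are drawn from the mid/high terciles and
    zeroed in a random majority (>= 60%) of animals.  Only the targeted rows
    change, and column depths move by far less than 1%.
    """
    if n_above < 0 or n_below < 0:
        raise ValueError("n_above and n_below must be >= 0")
    if n_above + n_below > cm.n_sgb:
        raise ValueError("cannot select more taxa than SGBs present")
    rng = np.random.default_rng(seed)
    low, _ = _eligible_terciles(truth.p_meta)
    midhigh = _eligible_below(truth.p_meta, n_below)
    if n_above > low.size:
        raise ValueError(
            f"only {low.size} bottom-tercile SGBs available for n_above={n_above}"
        )
    if n_below > midhigh.size:
        raise ValueError(
            f"only {midhigh.size} mid/high-tercile SGBs are rare enough to zero "
            f"within the depth budget; n_below={n_below} requested"
        )
    above_idx = rng.choice(low, size=n_above, replace=False) if n_above else np.array([], int)
    midhigh_pool = np.setdiff1d(midhigh, above_idx, assume_unique=True)
    below_idx = rng.choice(midhigh_pool, size=n_below, replace=False) if n_below else np.array([], int)
    counts = cm.counts.copy()
    apply_selection(counts, above_idx, below_idx, cm.n_samples, rng)
    new_truth = replace(
        truth,
        selected_above=set(truth.selected_above) | {cm.sgb_ids[i] for i in above_idx},
        selected_below=set(truth.selected_below) | {cm.sgb_ids[i] for i in below_idx},
    )
    return CountMatrix(list(cm.sgb_ids), list(cm.sample_ids), counts), new_truth


def apply_selection(counts: np.ndarray, above_idx: np.ndarray,
                    below_idx: np.ndarray, n_animals: int,
                    rng: np.random.Generator) -> None:
    """In-place occupancy rewrite shared by :func:`inject_selection` and
    :func:`simulate_study` (which must target the same rows at every
    timepoint so selection persists per animal group)."""
    for i in above_idx:
        row = counts[i]
        row[row == 0] = 1
    min_zero = int(np.ceil(0.6 * n_animals))
    for i in below_idx:
        k = int(rng.integers(min_zero, n_animals + 1))
        cols = rng.choice(n_animals, size=k, replace=False)
        counts[i, cols] = 0


@dataclass
class StudyDesign:
    """Design of a simulated two-group longitudinal study.

    Defaults mirror a 2 feed-efficiency-group x 4 timepoint bull study with
    10 animals per cell (5 forage-fed, 5 grain-fed per group).
    """

    n_animals_per_cell: int = 10
    timepoints: tuple[str, ...] = TIMEPOINTS
    Nm_by_group: dict[str, float] = field(
        default_factory=lambda: {"HFE": 1.1e5, "LFE": 1.35e5}
    )
    selection_by_group: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"HFE": (0, 0), "LFE": (0, 0)}
    )
    n_sgb: int = 2000
    depth_mean: float = 1e5
    abundance_shape: float = 2.0
    selected_genus: str = "SelectedPos"
    n_background_genera: int = 20

    def __post_init__(self) -> None:
        if len(self.Nm_by_group) != 2:
            raise ValueError("design must name exactly 2 fe_groups")
        if not self.timepoints:
            raise ValueError("design needs >=1 timepoint")
        if set(self.selection_by_group) - set(self.Nm_by_group):
            raise ValueError("selection_by_group names unknown groups")


def simulate_study(
    design: StudyDesign, seed: int = 0
) -> tuple[CountMatrix, SampleMetadata, TaxonomyTable, dict[tuple[str, str], SimTruth]]:
    """Simulate a full study: per-(group, timepoint) neutral slices from a
    shared metacommunity, persistent animal identities across timepoints,
    persistent selected-taxon sets within each group, and genus labels that
    concentrate the positively selected taxa in one designated genus.

    Returns the combined count matrix, metadata, taxonomy and a per-slice
    truth dict keyed by ``(fe_group, timepoint)``.
    """
    rng = np.random.default_rng(seed)
    n = design.n_sgb
    raw = rng.lognormal(0.0, design.abundance_shape, size=n)
    p_meta = raw / raw.sum()
    sgb_ids = [f"SGB{i:05d}" for i in range(n)]

    groups = sorted(design.Nm_by_group)
    # choose persistent selection targets per group
    targets: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    low, _ = _eligible_terciles(p_meta)
    for g in groups:
        n_above, n_below = design.selection_by_group.get(g, (0, 0))
        midhigh = _eligible_below(p_meta, n_below)
        if n_above > low.size or n_below > midhigh.size:
            raise ValueError(f"group {g}: not enough eligible SGBs for selection")
        above = rng.choice(low, size=n_above, replace=False) if n_above else np.array([], int)
        pool = np.setdiff1d(midhigh, above, assume_unique=True)
        below = rng.choice(pool, size=n_below, replace=False) if n_below else np.array([], int)
        targets[g] = (above, below)

    blocks: list[np.ndarray] = []
    sample_ids: list[str] = []
    meta_rows: list[dict[str, str]] = []
    truths: dict[tuple[str, str], SimTruth] = {}
    for g in groups:
        animals = [f"{g}_A{k:02d}" for k in range(design.n_animals_per_cell)]
        diets = ["F" if k < design.n_animals_per_cell / 2 else "G"
                 for k in range(design.n_animals_per_cell)]
        above_idx, below_idx = targets[g]
        nm = design.Nm_by_group[g]
        alpha, beta = nm * p_meta, nm * (1.0 - p_meta)
        if alpha.min() <= 0:
            raise ValueError("Nm * p_i underflowed; increase Nm or reduce n_sgb")
        for tp in design.timepoints:
            local = rng.beta(alpha[:, None], beta[:, None],
                             size=(n, design.n_animals_per_cell))
            local /= local.sum(axis=0, keepdims=True)
            depths = rng.poisson(design.depth_mean, size=design.n_animals_per_cell)
            counts = np.empty((n, design.n_animals_per_cell), dtype=np.int64)
            for j in range(design.n_animals_per_cell):
                counts[:, j] = rng.multinomial(depths[j], local[:, j])
            apply_selection(counts, above_idx, below_idx,
                            design.n_animals_per_cell, rng)
            blocks.append(counts)
            for k, a in enumerate(animals):
                sample_ids.append(f"{a}_{tp}")
                meta_rows.append({"animal_id": a, "diet": diets[k],
                                  "fe_group": g, "timepoint": tp})
            truths[(g, tp)] = SimTruth(
                Nm_true=float(nm), p_meta=p_meta,
                selected_above={sgb_ids[i] for i in above_idx},
                selected_below={sgb_ids[i] for i in below_idx},
                depth_mean=float(design.depth_mean), seed=seed,
            )
    cm = CountMatrix(sgb_ids, sample_ids, np.concatenate(blocks, axis=1))
    md = SampleMetadata(pd.DataFrame(meta_rows, index=sample_ids))

    # taxonomy: positively selected taxa (any group) in one designated genus,
    # everything else spread over background genera
    all_above = set().union(*(set(t[0].tolist()) for t in targets.values()))
    lineages = {}
    for i, sgb in enumerate(sgb_ids):
        if i in all_above:
            genus = design.selected_genus
        else:
            genus = f"Bg{i % design.n_background_genera:02d}"
        lineages[sgb] = (
            "d__Bacteria;p__SimPhylum;c__SimClass;o__SimOrder;"
            f"f__SimFamily;g__{genus};s__{genus} sp{i:05d}"
        )
    return cm, md, TaxonomyTable(lineages), truths


# ---------------------------------------------------------------------------
# CAZyme domain-architecture generator
# ---------------------------------------------------------------------------

_CBM_POOL = ["CBM2", "CBM3", "CBM6", "CBM9", "CBM11", "CBM13", "CBM26",
             "CBM32", "CBM86", "CBM91"]
_CATALYTIC_POOL = ["GH5", "GH10", "GH13", "GH29", "GH43", "GH43_10", "GH43_16",
                   "GH43_29", "GH51", "PL1", "PL9", "CE1", "CE6", "AA3", "AA10"]
_OTHER_POOL = ["SLH", "DOC", "COH", "FN3", "UNK1"]


def simulate_domain_annotations(
    n_genomes: int,
    n_proteins_per_genome: int,
    cbm_rich_fraction: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Random per-protein domain architectures for ``n_genomes`` genomes.

    A ``cbm_rich_fraction`` of genomes is flagged CBM-rich: their proteins
    have an elevated chance of carrying a tandem CBM run of length 2-3
    adjacent to a catalytic (GH) domain — the architecture motif of interest.
    Returns a DataFrame with columns protein_id, genome_id, architecture,
    cbm_rich; architectures are '+'-joined token strings.
    """
    if n_genomes < 1 or n_proteins_per_genome < 1:
        raise ValueError("counts must be >= 1")
    if not 0.0 <= cbm_rich_fraction <= 1.0:
        raise ValueError("cbm_rich_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_rich = int(round(cbm_rich_fraction * n_genomes))
    rich_flags = np.array([True] * n_rich + [False] * (n_genomes - n_rich))
    rng.shuffle(rich_flags)
    rows = []
    for g in range(n_genomes):
        genome = f"G{g:03d}"
        rich = bool(rich_flags[g])
        p_tandem = 0.25 if rich else 0.02
        p_cbm_single = 0.15 if rich else 0.05
        for k in range(n_proteins_per_genome):
            tokens: list[str] = []
            u = rng.random()
            if u < p_tandem:
                run_len = int(rng.integers(2, 4))
                cbm = str(rng.choice(_CBM_POOL))
                tokens = [cbm] * run_len + [str(rng.choice(_CATALYTIC_POOL))]
                if rng.random() < 0.3:
                    tokens.append(str(rng.choice(_OTHER_POOL)))
            elif u < p_tandem + p_cbm_single:
                tokens = [str(rng.choice(_CBM_POOL)), str(rng.choice(_CATALYTIC_POOL))]
            else:
                n_tok = int(rng.integers(1, 4))
                pool = _CATALYTIC_POOL + _OTHER_POOL
                tokens = [str(rng.choice(pool)) for _ in range(n_tok)]
            rows.append({
                "protein_id": f"{genome}_P{k:05d}",
                "genome_id": genome,
                "architecture": "+".join(tokens),
                "cbm_rich": rich,
            })
    return pd.DataFrame(rows)
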