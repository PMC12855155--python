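"""Animal-level bootstrap for NCM estimates and random-effects pooling.

Uncertainty in the fitted immigration parameter Nm and in R² is obtained by
resampling animals (slice columns) with replacement and re-running the full
per-slice analysis — recomputing metacommunity abundances, occurrence
frequencies, community size and detection limit before refitting — so each
replicate is a complete re-analysis of a plausible alternative animal set.

Per-timepoint estimates are then pooled per feed-efficiency group with a
DerSimonian–Laird random-effects meta-analysis: Nm on the natural-log scale
(back-transformed for reporting), R² on the linear scale, with bootstrap
squared standard errors as the within-timepoint variances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import ncm
from .study_io import (CountMatrix, SampleMetadata, SliceSpec,
                       canonical_slices, slice_group_timepoint)

__all__ = [
    "BootstrapDistribution",
    "PooledEstimate",
    "bootstrap_ncm",
    "pool_random_effects",
    "run_ncm_study",
]

#: replicate-failure fraction beyond which a bootstrap is flagged unreliable
MAX_FAILED_FRACTION = 0.20


@dataclass
class BootstrapDistribution:
    """Bootstrap replicates of one statistic with percentile CI and SE."""

    statistic: str  # "Nm" or "r_squared"
    replicates: np.ndarray
    point: float
    ci_lower: float
    ci_upper: float
    se: float
    n_failed: int
    seed: int
    unreliable: bool = False

    def __post_init__(self) -> None:
        if self.ci_lower > self.ci_upper:
            raise ValueError("bootstrap CI bounds out of order")


@dataclass
class PooledEstimate:
    """DerSimonian–Laird random-effects pooled estimate across timepoints."""

    scale: str  # "log" or "linear"
    estimates: np.ndarray  # per-timepoint, on the pooling scale
    variances: np.ndarray
    pooled: float          # back-transformed when scale == "log"
    pooled_scale_value: float  # on the pooling scale
    ci_lower: float
    ci_upper: float
    se: float
    tau_squared: float
    method: str = "DerSimonian-Laird"
    note: str = ""


def bootstrap_ncm(
    slice_cm: CountMatrix,
    B: int = 1000,
    seed: int = 0,
    min_sgb: int = 10,
    level: float = 0.95,
) -> tuple[BootstrapDistribution, BootstrapDistribution]:
    """Animal-level bootstrap of the per-slice NCM fit.

    Each replicate resamples the slice's animal columns with replacement
    (same animal count), recomputes p, F, N, d from the resample and refits.
    Replicates that leave fewer than ``min_sgb`` fittable SGBs, fail to
    converge, or have undefined R² are dropped and counted.  Replicate fits
    warm-start from the point estimate (single start) for speed; the point
    fit itself uses the full multi-start schedule.
    """
    rng = np.random.default_rng(seed)
    inp = ncm.prepare_ncm_input(slice_cm)
    fit = ncm.fit_ncm(inp, min_sgb=min_sgb, level=level)
    warm = (float(np.log(fit.Nm)),)
    n = slice_cm.n_samples
    nm_reps: list[float] = []
    r2_reps: list[float] = []
    n_failed_nm = 0
    n_failed_r2 = 0
    for _ in range(B):
        cols = rng.integers(0, n, size=n)
        counts = slice_cm.counts[:, cols]
        try:
            rinp = _prepare_from_counts(counts, slice_cm.sgb_ids)
            if rinp.p.size < min_sgb:
                raise ValueError("too few fittable SGBs in resample")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rfit = ncm.fit_ncm(rinp, min_sgb=min_sgb, level=level, starts=warm)
            if not rfit.converged:
                raise ValueError("replicate fit did not converge")
        except (ValueError, FloatingPointError):
            n_failed_nm += 1
            n_failed_r2 += 1
            continue
        nm_reps.append(rfit.Nm)
        # R^2 can be undefined (all frequencies identical) on a resample whose
        # Nm fit is still valid; the streams are accounted separately
        if np.isfinite(rfit.r_squared):
            r2_reps.append(rfit.r_squared)
        else:
            n_failed_r2 += 1
    unreliable = max(n_failed_nm, n_failed_r2) > MAX_FAILED_FRACTION * B
    if unreliable:
        warnings.warn(
            f"{max(n_failed_nm, n_failed_r2)}/{B} bootstrap replicates failed; "
            "results flagged unreliable"
        )
    return (
        _summarize("Nm", np.asarray(nm_reps), fit.Nm, n_failed_nm, seed,
                   n_failed_nm > MAX_FAILED_FRACTION * B),
        _summarize("r_squared", np.asarray(r2_reps), fit.r_squared,
                   n_failed_r2, seed, n_failed_r2 > MAX_FAILED_FRACTION * B),
    )


def _prepare_from_counts(counts: np.ndarray, sgb_ids: Sequence[str]) -> ncm.NCMInput:
    """prepare_ncm_input on a raw resampled column array (avoids re-validating
    a CountMatrix per replicate; duplicated sample ids are expected here)."""
    total = counts.sum()
    if total == 0:
        raise ValueError("resample contains no reads")
    N = float(counts.sum(axis=0).mean())
    if N < 2:
        raise ValueError("degenerate resample depth")
    p = counts.sum(axis=1) / total
    F = (counts >= 1).mean(axis=1)
    keep = F > 0
    return ncm.NCMInput(
        sgb_ids=[s for s, k in zip(sgb_ids, keep) if k],
        p=p[keep], F=F[keep],
        n_samples=counts.shape[1], N=N, d=1.0 / N,
    )


def _summarize(name: str, reps: np.ndarray, point: float, n_failed: int,
               seed: int, unreliable: bool) -> BootstrapDistribution:
    if reps.size == 0:
        return BootstrapDistribution(name, reps, point, float("nan"), float("nan"),
                                     float("nan"), n_failed, seed, True)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    se = float(reps.std(ddof=1)) if reps.size > 1 else 0.0
    return BootstrapDistribution(name, reps, float(point), float(lo), float(hi),
                                 se, n_failed, seed, unreliable)


def pool_random_effects(
    estimates: Sequence[float],
    variances: Sequence[float],
    scale: str = "linear",
) -> PooledEstimate:
    """DerSimonian–Laird random-effects pooling of per-timepoint estimates.

    For ``scale="log"`` the inputs must already be log-scale estimates with
    log-scale variances; the pooled value is exponentiated for reporting
    (``pooled_scale_value`` keeps the log-scale mean).  Heterogeneity:
    Q = sum w_k (y_k - y_FE)^2 with fixed weights w_k = 1/v_k, and
    tau^2 = max(0, (Q - (K-1)) / (sum w - sum w^2 / sum w)).
    """
    if scale not in ("log", "linear"):
        raise ValueError("scale must be 'log' or 'linear'")
    y = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    if y.size == 0:
        raise ValueError("need >=1 estimate to pool")
    if y.shape != v.shape:
        raise ValueError("estimates and variances must have equal length")
    if np.any(v <= 0):
        raise ValueError("variances must be positive")
    K = y.size
    note = ""
    if K == 1:
        mu, se2, tau2 = float(y[0]), float(v[0]), 0.0
        note = "single timepoint: no heterogeneity estimable"
    else:
        w = 1.0 / v
        mu_fe = float(np.sum(w * y) / np.sum(w))
        Q = float(np.sum(w * (y - mu_fe) ** 2))
        denom = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))
        tau2 = max(0.0, (Q - (K - 1)) / denom) if denom > 0 else 0.0
        w_re = 1.0 / (v + tau2)
        mu = float(np.sum(w_re * y) / np.sum(w_re))
        se2 = float(1.0 / np.sum(w_re))
    z = stats.norm.ppf(0.975)
    se = float(np.sqrt(se2))
    lo, hi = mu - z * se, mu + z * se
    if scale == "log":
        return PooledEstimate("log", y, v, float(np.exp(mu)), mu,
                              float(np.exp(lo)), float(np.exp(hi)), se, tau2,
                              note=note)
    return PooledEstimate("linear", y, v, mu, mu, float(lo), float(hi), se,
                          tau2, note=note)


@dataclass
class SliceResult:
    spec: SliceSpec
    fit: ncm.NCMFit
    partitions: pd.DataFrame
    boot_nm: BootstrapDistribution
    boot_r2: BootstrapDistribution


@dataclass
class StudyReport:
    """Full per-group NCM study: per-slice fits and per-group pooled values."""

    slices: dict[tuple[str, str], SliceResult]
    pooled_nm: dict[str, PooledEstimate]
    pooled_r2: dict[str, PooledEstimate]
    skipped: dict[tuple[str, str], str] = field(default_factory=dict)

    def summary_dict(self) -> dict:
        out: dict = {"groups": {}, "slices": {}, "skipped": {
            f"{g}:{tp}": why for (g, tp), why in sorted(self.skipped.items())}}
        for (g, tp), res in sorted(self.slices.items()):
            counts = ncm.partition_counts(res.partitions)
            n_fit = len(res.partitions)
            out["slices"][f"{g}:{tp}"] = {
                "Nm": res.fit.Nm,
                "Nm_ci": [res.boot_nm.ci_lower, res.boot_nm.ci_upper],
                "r_squared": res.fit.r_squared,
                "r_squared_ci": [res.boot_r2.ci_lower, res.boot_r2.ci_upper],
                "n_fitted_sgb": n_fit,
                "partition_counts": counts,
                "partition_proportions": {
                    k: c / n_fit for k, c in counts.items()},
                "bootstrap_failed": res.boot_nm.n_failed,
                "bootstrap_unreliable": res.boot_nm.unreliable,
            }
        for g in sorted(self.pooled_nm):
            pn, pr = self.pooled_nm[g], self.pooled_r2[g]
            out["groups"][g] = {
                "Nm": pn.pooled, "Nm_ci": [pn.ci_lower, pn.ci_upper],
                "Nm_tau_squared": pn.tau_squared,
                "r_squared": min(pr.pooled, 1.0),
                "r_squared_ci": [pr.ci_lower, min(pr.ci_upper, 1.0)],
                "r_squared_tau_squared": pr.tau_squared,
                "method": pn.method,
            }
        return out


def run_ncm_study(
    cm: CountMatrix,
    md: SampleMetadata,
    B: int = 1000,
    seed: int = 0,
    min_sgb: int = 10,
    level: float = 0.95,
) -> StudyReport:
    """Fit + partition + bootstrap every (fe_group, timepoint) slice, then
    pool Nm (log scale) and R² (linear scale) per group across timepoints.

    Slices failing their preconditions are recorded as skipped and the study
    continues.  All per-slice bootstrap seeds derive deterministically from
    ``seed``.
    """
    specs = canonical_slices(md)
    slices: dict[tuple[str, str], SliceResult] = {}
    skipped: dict[tuple[str, str], str] = {}
    children = np.random.SeedSequence(seed).spawn(len(specs))
    for spec, child in zip(specs, children):
        key = (spec.fe_group, spec.timepoint)
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        try:
            sl = slice_group_timepoint(cm, md, spec)
            inp = ncm.prepare_ncm_input(sl)
            fit = ncm.fit_ncm(inp, min_sgb=min_sgb, level=level)
            parts = ncm.classify_partitions(inp, fit)
            bnm, br2 = bootstrap_ncm(sl, B=B, seed=sub_seed,
                                     min_sgb=min_sgb, level=level)
        except ValueError as exc:
            skipped[key] = str(exc)
            continue
        slices[key] = SliceResult(spec, fit, parts, bnm, br2)

    pooled_nm: dict[str, PooledEstimate] = {}
    pooled_r2: dict[str, PooledEstimate] = {}
    for g in sorted({k[0] for k in slices}):
        results = [slices[k] for k in sorted(slices) if k[0] == g]
        log_nm, log_nm_var, r2, r2_var = [], [], [], []
        for res in results:
            reps = res.boot_nm.replicates
            if reps.size < 2 or res.boot_r2.replicates.size < 2:
                continue
            log_nm.append(float(np.log(res.fit.Nm)))
            log_nm_var.append(float(np.log(reps).var(ddof=1)))
            r2.append(res.fit.r_squared)
            r2_var.append(float(res.boot_r2.replicates.var(ddof=1)))
        if not log_nm:
            continue
        pooled_nm[g] = pool_random_effects(log_nm, log_nm_var, scale="log")
        pooled_r2[g] = pool_random_effects(r2, r2_var, scale="linear")
    return StudyReport(slices, pooled_nm, pooled_r2, skipped)
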