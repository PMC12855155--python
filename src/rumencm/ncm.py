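"""Sloan neutral community model (NCM) for SGB occurrence frequencies.

The model treats each animal's rumen community as a local community of mean
size ``N`` reads, assembled from a shared metacommunity by drift and
immigration.  For an SGB with metacommunity relative abundance ``p_i``, the
stationary distribution of its local relative abundance is
``Beta(Nm * p_i, Nm * (1 - p_i))`` where ``Nm`` (community size times
immigration probability) is the single free parameter.  The probability of
detecting the SGB in an animal — its expected occurrence frequency — is the
upper tail of that Beta above the detection limit ``d = 1/N`` (one read):

    F_hat_i = 1 - BetaCDF(d; alpha=Nm*p_i, beta=Nm*(1-p_i))

``Nm`` is estimated by nonlinear least squares (Levenberg–Marquardt) on the
observed occurrence frequencies, goodness of fit by the coefficient of
determination, and each SGB is classified against a 95% Wilson score band
around its predicted frequency: observed frequency above the band indicates
positive selection, below indicates negative selection, inside is consistent
with stochastic (neutral) assembly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .study_io import CountMatrix

__all__ = [
    "NCMInput",
    "NCMFit",
    "prepare_ncm_input",
    "expected_frequency",
    "fit_ncm",
    "wilson_band",
    "classify_partitions",
]

#: natural-log Nm starting points for the multi-start fit (Nm ~ 7 to 3000)
DEFAULT_STARTS = (2.0, 4.0, 6.0, 8.0)
PARTITION_LABELS = ("above", "neutral", "below")


@dataclass
class NCMInput:
    """Per-slice observations entering the fit.

    ``p`` and ``F`` cover the fit set only: SGBs undetected in the slice
    (occurrence frequency 0, hence no abundance estimate) are listed in
    ``dropped`` and excluded.  ``N`` is the arithmetic mean of per-sample
    total read counts and ``d = 1/N`` the detection limit.  The immigration
    probability ``m`` is implicit: ``m = Nm / N``.
    """

    sgb_ids: list[str]
    p: np.ndarray
    F: np.ndarray
    n_samples: int
    N: float
    d: float
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.p.shape != self.F.shape or self.p.ndim != 1:
            raise ValueError("p and F must be 1-D arrays of equal length")
        if self.p.size and (self.p.min() <= 0 or self.p.sum() > 1 + 1e-9):
            raise ValueError("p_i must be positive with sum <= 1")
        if self.F.size and (self.F.min() <= 0 or self.F.max() > 1):
            raise ValueError("F_i must lie in (0, 1]")
        if not (0 < self.d < 1):
            raise ValueError("detection limit d must lie in (0, 1)")


@dataclass
class NCMFit:
    """Fitted model: Nm, goodness of fit, predictions and the Wilson band."""

    Nm: float
    r_squared: float
    F_hat: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray
    converged: bool
    n_iterations: int
    sse: float
    level: float = 0.95
    message: str = ""


def prepare_ncm_input(slice_cm: CountMatrix) -> NCMInput:
    """Compute metacommunity abundances and occurrence frequencies for a slice.

    ``p_i = sum_j a_ij / sum_ij a_ij`` over raw counts of the slice;
    ``F_i`` is the fraction of animals with at least one read of SGB i.
    """
    counts = slice_cm.counts
    if slice_cm.n_samples < 2:
        raise ValueError("need >=2 samples to compute occurrence frequencies")
    total = counts.sum()
    if total == 0:
        raise ValueError("slice contains no reads")
    depths = counts.sum(axis=0)
    N = float(depths.mean())
    if N < 2:
        raise ValueError(f"degenerate mean community size N={N}")
    p = counts.sum(axis=1) / total
    F = (counts >= 1).mean(axis=1)
    keep = F > 0
    dropped = [s for s, k in zip(slice_cm.sgb_ids, keep) if not k]
    return NCMInput(
        sgb_ids=[s for s, k in zip(slice_cm.sgb_ids, keep) if k],
        p=p[keep],
        F=F[keep],
        n_samples=slice_cm.n_samples,
        N=N,
        d=1.0 / N,
        dropped=dropped,
    )


def expected_frequency(p: np.ndarray, Nm: float, d: float) -> np.ndarray:
    """Neutral prediction ``1 - BetaCDF(d; Nm*p, Nm*(1-p))`` elementwise."""
    p = np.asarray(p, dtype=float)
    if Nm <= 0:
        raise ValueError("Nm must be positive")
    if not (0 < d < 1):
        raise ValueError("d must lie in (0, 1)")
    if p.size and (p.min() <= 0 or p.max() >= 1):
        raise ValueError("p_i must lie strictly inside (0, 1)")
    return stats.beta.sf(d, Nm * p, Nm * (1.0 - p))


def wilson_band(F_hat: np.ndarray, n: int, level: float = 0.95
                ) -> tuple[np.ndarray, np.ndarray]:
    """Wilson score interval around each predicted frequency.

    Treats the predicted frequency as a binomial proportion observed over
    ``n`` animals (the slice's sample count).  The Wilson interval is used
    rather than the Wald interval because it behaves sensibly near 0 and 1,
    where most SGB frequencies sit.
    """
    if n < 2:
        raise ValueError("Wilson band requires n >= 2 animals")
    F_hat = np.asarray(F_hat, dtype=float)
    if F_hat.size and (F_hat.min() < 0 or F_hat.max() > 1):
        raise ValueError("F_hat must lie in [0, 1]")
    z = stats.norm.ppf(0.5 * (1.0 + level))
    z2 = z * z
    denom = 1.0 + z2 / n
    center = (F_hat + z2 / (2.0 * n)) / denom
    half = z * np.sqrt(F_hat * (1.0 - F_hat) / n + z2 / (4.0 * n * n)) / denom
    lower = np.clip(center - half, 0.0, 1.0)
    upper = np.clip(center + half, 0.0, 1.0)
    # in exact arithmetic the upper bound equals 1 when F_hat == 1 (and the
    # lower equals 0 when F_hat == 0); snap away float rounding at the edges
    # so boundary observations compare as ties, not exceedances
    upper[1.0 - upper < 1e-12] = 1.0
    lower[lower < 1e-12] = 0.0
    return lower, upper


def fit_ncm(inp: NCMInput, min_sgb: int = 10, level: float = 0.95,
            starts: tuple[float, ...] = DEFAULT_STARTS) -> NCMFit:
    """Estimate Nm by Levenberg–Marquardt least squares on log(Nm).

    The optimization is parameterized on log(Nm) so positivity is implicit
    and the scale is well conditioned; four starting values spanning
    Nm ~ 10..3000 guard against local minima, and the best SSE wins.  R² is
    the plain coefficient of determination on frequencies and is not clamped:
    a negative value (model worse than the mean) is reported as-is.
    """
    if inp.p.size < min_sgb:
        raise ValueError(
            f"only {inp.p.size} SGBs in fit set; minimum is {min_sgb}"
        )
    p, F, d = inp.p, inp.F, inp.d

    def residuals(theta: np.ndarray) -> np.ndarray:
        return F - stats.beta.sf(d, np.exp(theta[0]) * p, np.exp(theta[0]) * (1.0 - p))

    best = None
    n_iter = 0
    for x0 in starts:
        try:
            res = optimize.least_squares(residuals, [float(x0)], method="lm")
        except Exception:  # LM can fail on pathological starts
            continue
        n_iter += res.nfev
        if res.status > 0 and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        # fallback: bounded scalar minimization of the SSE
        obj = lambda t: float(np.sum(residuals([t]) ** 2))
        scal = optimize.minimize_scalar(obj, bounds=(-5.0, 30.0), method="bounded")
        nm = float(np.exp(scal.x))
        f_hat = expected_frequency(p, nm, d)
        lower, upper = wilson_band(f_hat, inp.n_samples, level)
        return NCMFit(nm, _r_squared(F, f_hat), f_hat, lower, upper,
                      converged=bool(scal.success), n_iterations=n_iter + scal.nfev,
                      sse=float(scal.fun), level=level,
                      message="LM failed from all starts; bounded scalar fallback")
    nm = float(np.exp(best.x[0]))
    f_hat = expected_frequency(p, nm, d)
    lower, upper = wilson_band(f_hat, inp.n_samples, level)
    return NCMFit(
        Nm=nm,
        r_squared=_r_squared(F, f_hat),
        F_hat=f_hat,
        band_lower=lower,
        band_upper=upper,
        converged=True,
        n_iterations=n_iter,
        sse=float(2.0 * best.cost),
        level=level,
        message=best.message,
    )


def _r_squared(F: np.ndarray, F_hat: np.ndarray) -> float:
    ss_res = float(np.sum((F - F_hat) ** 2))
    ss_tot = float(np.sum((F - F.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("all observed frequencies identical; R^2 undefined")
        return float("nan")
    r2 = 1.0 - ss_res / ss_tot
    if r2 < 0:
        warnings.warn(f"negative R^2 ({r2:.3f}): model fits worse than the mean")
    return r2


def classify_partitions(inp: NCMInput, fit: NCMFit) -> pd.DataFrame:
    """Label each fitted SGB above / neutral / below the Wilson band.

    Strict inequalities: observed frequency exactly on a band bound counts
    as neutral.  Above the band is read as positive selection, below as
    negative selection, inside as stochastic assembly.
    """
    if not fit.converged:
        raise ValueError("cannot classify partitions from a non-converged fit")
    label = np.where(
        inp.F > fit.band_upper, "above",
        np.where(inp.F < fit.band_lower, "below", "neutral"),
    )
    return pd.DataFrame(
        {
            "sgb_id": inp.sgb_ids,
            "p": inp.p,
            "F": inp.F,
            "F_hat": fit.F_hat,
            "lower": fit.band_lower,
            "upper": fit.band_upper,
            "label": label,
        }
    )


def partition_counts(table: pd.DataFrame) -> dict[str, int]:
    return {lab: int((table["label"] == lab).sum()) for lab in PARTITION_LABELS}
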