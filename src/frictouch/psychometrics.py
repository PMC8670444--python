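"""Two-alternative forced-choice (2AFC) friction-discrimination analysis.

In the discrimination task the observer presses twice — once on a
reference surface (highest friction, vibration amplitude essentially
zero) and once on a comparison surface whose friction is lowered by
ultrasonic lubrication at amplitude ``alpha`` — and reports which felt
more slippery.  Chance performance is 0.5.  The proportion of "the
comparison was more slippery" responses versus ``alpha`` is fitted
with a psychometric function

    psi(x) = gamma + (1 - gamma - lambda) * Phi((x - m)/s)

with guess rate ``gamma = 0.5``, a small fixed lapse rate ``lambda``
and a cumulative-Gaussian core ``Phi``.  The 75 %-correct point of the
fitted curve is the discrimination threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm, spearmanr

from .errors import DataError, ParameterError

__all__ = [
    "TwoAfcDataset",
    "PsychometricFit",
    "proportion_table",
    "fit_psychometric",
    "threshold_75",
    "discrimination_vs_divergence",
]

#: Fixed lapse rate of the psychometric model.
DEFAULT_LAPSE = 0.02
#: Chance level of a 2AFC task.
GUESS_RATE = 0.5


@dataclass
class TwoAfcDataset:
    """Per-level response counts of one (or a pool of) 2AFC observers."""

    comparison_levels: np.ndarray  # vibration amplitudes, um, increasing
    n_trials: np.ndarray
    n_correct: np.ndarray  # "comparison most slippery" responses
    participant: str = "pooled"
    reference_level: float = 1e-3  # um

    def __post_init__(self) -> None:
        self.comparison_levels = np.asarray(self.comparison_levels, dtype=float)
        self.n_trials = np.asarray(self.n_trials, dtype=int)
        self.n_correct = np.asarray(self.n_correct, dtype=int)
        if not (
            self.comparison_levels.shape
            == self.n_trials.shape
            == self.n_correct.shape
        ):
            raise DataError("levels, trials and correct counts must align")
        if np.any(np.diff(self.comparison_levels) <= 0):
            raise DataError("comparison levels must be strictly increasing")
        if np.any(self.n_correct < 0) or np.any(self.n_correct > self.n_trials):
            raise DataError("need 0 <= n_correct <= n_trials at every level")
        if self.comparison_levels.size and self.reference_level >= float(
            self.comparison_levels[0]
        ):
            raise DataError("reference level must lie below all comparison levels")

    @property
    def proportions(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.n_trials > 0, self.n_correct / self.n_trials, np.nan)


@dataclass
class PsychometricFit:
    """A fitted 2AFC psychometric curve and its 75 % threshold."""

    threshold_75: float
    slope: float  # 1/um, derivative of psi at the threshold
    location: float  # m, um
    spread: float  # s, um
    lapse: float
    guess: float
    fitted_probabilities: np.ndarray
    converged: bool
    extrapolated: bool = False
    log_likelihood: float = np.nan
    dataset: TwoAfcDataset = _dc_field(default=None, repr=False)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """psi(x) of the fitted curve."""
        return _psi(np.asarray(x, dtype=float), self.location, self.spread,
                    self.guess, self.lapse)


def _psi(x: np.ndarray, m: float, s: float, guess: float, lapse: float) -> np.ndarray:
    return guess + (1.0 - guess - lapse) * norm.cdf((x - m) / s)


def proportion_table(
    responses: pd.DataFrame,
    participant: str = "pooled",
    reference_level: float = 1e-3,
) -> TwoAfcDataset:
    """Aggregate raw 2AFC responses into per-level counts.

    ``responses`` needs columns ``level_um`` and ``chose_comparison``
    (boolean: the comparison was called most slippery).  Presentation
    order is irrelevant and marginalised out; an empty frame yields an
    empty table.
    """
    required = {"level_um", "chose_comparison"}
    if not required.issubset(responses.columns):
        raise DataError(f"responses must have columns {sorted(required)}")
    if len(responses) == 0:
        return TwoAfcDataset(
            comparison_levels=np.empty(0),
            n_trials=np.empty(0, dtype=int),
            n_correct=np.empty(0, dtype=int),
            participant=participant,
            reference_level=reference_level,
        )
    bad = responses["level_um"].isna() | ~np.isfinite(responses["level_um"])
    if bad.any():
        raise DataError("responses contain unknown/NaN level labels")
    grouped = responses.groupby("level_um")["chose_comparison"].agg(["count", "sum"])
    grouped = grouped.sort_index()
    return TwoAfcDataset(
        comparison_levels=grouped.index.to_numpy(dtype=float),
        n_trials=grouped["count"].to_numpy(dtype=int),
        n_correct=grouped["sum"].to_numpy(dtype=int),
        participant=participant,
        reference_level=reference_level,
    )


def threshold_75(
    location: float, spread: float, guess: float = GUESS_RATE,
    lapse: float = DEFAULT_LAPSE,
) -> float:
    """Stimulus level where the lapse-corrected curve crosses 0.75.

    Solves ``psi(x) = 0.75`` for the cumulative-Gaussian model:
    ``x = m + s * Phi^-1((0.75 - gamma)/(1 - gamma - lambda))``.
    """
    q = (0.75 - guess) / (1.0 - guess - lapse)
    if not 0.0 < q < 1.0:
        raise ParameterError("0.75 unreachable with these guess/lapse rates")
    return float(location + spread * norm.ppf(q))


def fit_psychometric(
    data: TwoAfcDataset,
    lapse: float = DEFAULT_LAPSE,
    guess: float = GUESS_RATE,
) -> PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit of a 2AFC dataset.

    The location and (log-)spread are optimised by Nelder-Mead on the
    binomial log-likelihood; guess and lapse rates are fixed.  Datasets
    carrying no information about a threshold — all responses at
    chance, or all correct — are returned with ``converged=False``
    (non-identifiable) and NaN threshold.  The threshold is flagged
    ``extrapolated`` when it falls outside the tested level range.
    """
    x = data.comparison_levels
    if x.size < 3 or int(data.n_trials.sum()) == 0:
        raise DataError("need at least 3 stimulus levels with trials")
    n = data.n_trials
    k = data.n_correct
    p_hat = k.sum() / n.sum()
    identifiable = (k < n).any() and (p_hat > 0.55)
    span = float(x[-1] - x[0])

    def nll(params: np.ndarray) -> float:
        m, log_s = params
        p = _psi(x, m, np.exp(log_s), guess, lapse)
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))

    best = None
    for m0 in (float(np.median(x)), float(x[0])):
        for s0 in (span / 2, span / 6):
            res = minimize(
                nll, np.array([m0, np.log(s0)]), method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 1500},
            )
            if best is None or res.fun < best.fun:
                best = res
    m, log_s = best.x
    s = float(np.exp(log_s))
    try:
        thr = threshold_75(m, s, guess, lapse)
    except ParameterError:
        thr = np.nan
    slope = float(
        (1.0 - guess - lapse) * norm.pdf((thr - m) / s) / s
    ) if np.isfinite(thr) else np.nan
    converged = bool(best.success and identifiable and np.isfinite(thr))
    extrapolated = bool(np.isfinite(thr)) and not (x[0] <= thr <= x[-1])
    return PsychometricFit(
        threshold_75=float(thr) if converged else np.nan,
        slope=slope,
        location=float(m),
        spread=s,
        lapse=lapse,
        guess=guess,
        fitted_probabilities=_psi(x, m, s, guess, lapse),
        converged=converged,
        extrapolated=extrapolated,
        log_likelihood=-best.fun,
        dataset=data,
    )


def discrimination_vs_divergence(
    divergence_difference: np.ndarray,
    chose_comparison: np.ndarray,
    n_bins: int = 6,
) -> dict:
    """Rank correlation of discrimination with the divergence cue.

    ``divergence_difference`` is the comparison-minus-reference mean
    divergence of each trial pair; ``chose_comparison`` the indicator
    that the comparison was called most slippery.  Returns the Spearman
    correlation (ties mid-ranked), its p-value, and an equal-count
    binned response curve.
    """
    d = np.asarray(divergence_difference, dtype=float)
    r = np.asarray(chose_comparison, dtype=float)
    if d.shape != r.shape or d.ndim != 1:
        raise DataError("paired 1-d arrays required")
    if d.size < 10:
        raise DataError("need at least 10 paired records")
    rho, p = spearmanr(d, r)
    edges = np.quantile(d, np.linspace(0, 1, n_bins + 1))
    edges[-1] = np.nextafter(edges[-1], np.inf)
    idx = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_bins - 1)
    centers = np.array([d[idx == b].mean() if (idx == b).any() else np.nan
                        for b in range(n_bins)])
    props = np.array([r[idx == b].mean() if (idx == b).any() else np.nan
                      for b in range(n_bins)])
    return {
        "spearman_rho": float(rho),
        "p_value": float(p),
        "bin_centers": centers,
        "bin_proportions": props,
    }
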