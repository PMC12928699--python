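"""Behavioural analyses: psychometrics, task d', and group statistics.

The behavioural session is summarised per participant and condition by a
maximum-likelihood cumulative-Gaussian psychometric fit of the proportion
of rightward responses versus stimulus location; sensitivity is the slope
at the point of subjective equality (PSE), ``1 / (sigma sqrt(2 pi))`` for
this family.  The MLE-predicted audiovisual slope is
``sqrt(slope_A^2 + slope_V^2)`` (slopes are proportional to 1/sigma and
reliabilities 1/sigma^2 add under optimal fusion).  The EEG-session task is
summarised by d' over left/right-majority judgements (tie sequences
excluded).  Group comparisons use the two-sided Wilcoxon signed-rank test
(normal approximation with continuity correction) and rank-order
correlations (Spearman's rho).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .metrics import dprime_from_rates

__all__ = [
    "PsychometricFit",
    "fit_psychometric",
    "mle_predicted_slope",
    "behavioural_dprime",
    "wilcoxon_signed_rank",
    "spearman_rho",
    "neurobehavioural_correlation",
]


@dataclass(frozen=True)
class PsychometricFit:
    """Cumulative-Gaussian psychometric fit.

    ``slope_at_pse`` (proportion per degree) is the sensitivity measure;
    for this family it equals ``(1 - lapse) / (sigma sqrt(2 pi))``.
    """

    pse: float
    sigma: float
    slope_at_pse: float
    loglik: float
    n_trials: int
    lapse: float = 0.0


def _psych_p(x: np.ndarray, pse: float, sigma: float, lapse: float) -> np.ndarray:
    return lapse / 2 + (1 - lapse) * stats.norm.cdf((x - pse) / sigma)


def fit_psychometric(
    locations_deg: np.ndarray,
    responses_rightward: np.ndarray,
    lapse: float = 0.0,
) -> PsychometricFit:
    """ML cumulative-Gaussian fit of rightward-response probability.

    ``lapse`` is fixed (default 0), not estimated.  Raises when responses
    carry no information (all identical) or fewer than two distinct
    locations are present.
    """
    x = np.asarray(locations_deg, dtype=float)
    y = np.asarray(responses_rightward).astype(float)
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct stimulus locations")
    if np.all(y == y[0]):
        raise ValueError("responses are all identical; psychometric fit is non-identifiable")

    def nll(theta):
        pse, log_sigma = theta
        p = _psych_p(x, pse, np.exp(log_sigma), lapse)
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return -np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))

    # moment-based start: probit regression through mean/SD of locations
    x0 = np.array([np.average(x, weights=None), np.log(max(np.std(x), 1.0))])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
    pse, sigma = res.x[0], float(np.exp(res.x[1]))
    slope = (1 - lapse) / (sigma * np.sqrt(2 * np.pi))
    return PsychometricFit(
        pse=float(pse), sigma=sigma, slope_at_pse=float(slope),
        loglik=-float(res.fun), n_trials=x.size, lapse=lapse,
    )


def mle_predicted_slope(slope_a: float, slope_v: float) -> float:
    """Predicted audiovisual psychometric slope sqrt(slope_A^2 + slope_V^2).

    Follows from slope = 1/(sigma sqrt(2 pi)) and optimal-fusion variances
    1/sigma_AV^2 = 1/sigma_A^2 + 1/sigma_V^2.
    """
    if slope_a < 0 or slope_v < 0:
        raise ValueError("slopes must be >= 0")
    return float(np.hypot(slope_a, slope_v))


def behavioural_dprime(trials: pd.DataFrame) -> float:
    """d' for the EEG-session left/right-majority task.

    ``trials`` needs columns ``true_side`` (+1 right, -1 left, 0 tie) and
    ``response_side`` (+1/-1).  Tie sequences (equal presentations on both
    sides) have no correct answer and are excluded.  Signal is "right":
    H = P(respond right | majority right), F = P(respond right | majority
    left); proportions are clipped to [1/(2N), 1 - 1/(2N)].
    """
    t = trials[trials["true_side"] != 0]
    right = t[t["true_side"] > 0]
    left = t[t["true_side"] < 0]
    if len(right) == 0 or len(left) == 0:
        raise ValueError("need non-tie sequences with majorities on both sides")
    H = (right["response_side"] > 0).mean()
    F = (left["response_side"] > 0).mean()
    return float(dprime_from_rates(H, F, len(right), len(left)))


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test; returns (Z, p).

    Convention: zero differences dropped, tied |differences| mid-ranked,
    continuity-corrected normal approximation (the convention under which
    a Z statistic is defined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n < 5:
        raise ValueError("need >= 5 non-zero differences")
    ranks = stats.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    mu = n * (n + 1) / 4
    var = n * (n + 1) * (2 * n + 1) / 24
    # tie correction on the midranks
    _, counts = np.unique(ranks, return_counts=True)
    var -= (counts**3 - counts).sum() / 48
    if var <= 0:
        raise ValueError("degenerate signed-rank variance (all differences tied at zero?)")
    diff = w_pos - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def spearman_rho(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with t-approximation p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("need n >= 5")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def neurobehavioural_correlation(
    decoding_dprime: np.ndarray,
    times: np.ndarray,
    behavioural_dprime_values: np.ndarray,
    window_s: tuple[float, float] = (0.15, 0.25),
) -> tuple[float, float]:
    """Spearman correlation between mean decoding d' in a window and behaviour.

    ``decoding_dprime`` is (participants, time); the decoding summary is the
    mean over ``window_s`` (150-250 ms by default).  No outlier rejection is
    performed (rank correlation is robust to outliers).
    """
    times = np.asarray(times, dtype=float)
    sel = (times >= window_s[0]) & (times < window_s[1])
    if not sel.any():
        raise ValueError(f"window {window_s} outside the time axis")
    summary = np.asarray(decoding_dprime, dtype=float)[:, sel].mean(axis=1)
    return spearman_rho(summary, np.asarray(behavioural_dprime_values, dtype=float))
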