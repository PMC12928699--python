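"""Mass-based cluster permutation correction for timecourse comparisons.

A pointwise paired (or one-sample) t-test is run at every timepoint;
contiguous runs of supra-threshold samples of equal sign form clusters whose
mass is the summed t within the run.  The family-wise null distribution of
the maximum cluster mass is simulated by randomly sign-flipping each
participant's difference timecourse (the participant is the exchangeable
unit); positive and negative clusters are tested against their own
matching-sign null at the 95th percentile.  When the number of distinct
sign patterns 2^n does not exceed the requested permutation count, the
exact enumeration is used instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["Cluster", "ClusterResult", "pointwise_t", "find_clusters",
           "permutation_null", "bank_permutation_null"]

logger = logging.getLogger(__name__)


@dataclass
class Cluster:
    """A maximal contiguous run of same-sign supra-threshold t values."""

    start: int               # first sample index (inclusive)
    end: int                 # last sample index (exclusive)
    sign: int                # +1 or -1
    mass: float              # summed t within the run (signed)
    p: float = float("nan")
    significant: bool = False
    start_time: float | None = None
    end_time: float | None = None


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    null_pos: np.ndarray      # per-permutation max positive cluster mass
    null_neg: np.ndarray      # per-permutation max |negative cluster mass|
    threshold_pos: float
    threshold_neg: float
    n_permutations: int
    seed: int | None
    exact: bool = False
    t_series: np.ndarray | None = None
    t_critical: float = float("nan")

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]


def pointwise_t(data_a: np.ndarray, data_b: np.ndarray | None = None,
                mu0: float = 0.0) -> np.ndarray:
    """Per-timepoint paired t (data_a vs data_b) or one-sample t against mu0.

    Arrays are (participants, time) with participants paired across
    conditions.  Timepoints with zero variance across participants yield
    t = 0 with a warning.
    """
    a = np.asarray(data_a, dtype=float)
    if data_b is not None:
        b = np.asarray(data_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired arrays must have identical shape")
        d = a - b
    else:
        d = a - mu0
    n = d.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants for a t-test")
    m = d.mean(axis=0)
    s = d.std(axis=0, ddof=1)
    zero = s == 0
    if np.any(zero):
        logger.warning("zero variance at %d timepoint(s); t set to 0", int(zero.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(zero, 0.0, m / (s / np.sqrt(n)))
    return t


def find_clusters(t_series: np.ndarray, df: int, alpha: float = 0.05,
                  times: np.ndarray | None = None) -> list[Cluster]:
    """Maximal contiguous supra-threshold runs of equal sign, with masses.

    The cluster-forming threshold is the two-sided t critical value at
    ``alpha`` for ``df`` degrees of freedom.
    """
    t_series = np.asarray(t_series, dtype=float)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    clusters: list[Cluster] = []
    for sign in (1, -1):
        sup = sign * t_series > tcrit
        edges = np.diff(sup.astype(int), prepend=0, append=0)
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        for s, e in zip(starts, ends):
            c = Cluster(start=int(s), end=int(e), sign=sign,
                        mass=float(t_series[s:e].sum()))
            if times is not None:
                c.start_time = float(times[s])
                c.end_time = float(times[e - 1])
            clusters.append(c)
    clusters.sort(key=lambda c: c.start)
    return clusters


def _max_cluster_masses(T_mat: np.ndarray, tcrit: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-row maximum positive cluster mass and |negative| cluster mass.

    Vectorised over rows by flattening with a sub-threshold separator column
    so runs never span rows.
    """
    R, T = T_mat.shape
    out = []
    for sign in (1, -1):
        X = sign * T_mat
        sup = np.concatenate([X > tcrit, np.zeros((R, 1), dtype=bool)], axis=1).ravel()
        vals = np.concatenate([np.where(sign * T_mat > tcrit, X, 0.0),
                               np.zeros((R, 1))], axis=1).ravel()
        edges = np.diff(sup.astype(int), prepend=0)
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        acc = np.zeros(R)
        if starts.size:
            csum = np.concatenate([[0.0], np.cumsum(vals)])
            masses = csum[ends] - csum[starts]
            rows = starts // (T + 1)
            np.maximum.at(acc, rows, masses)
        out.append(acc)
    return out[0], out[1]


def permutation_null(
    diffs: np.ndarray,
    n_perm: int = 5000,
    seed: int | None = 0,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    tail: str = "two",
    times: np.ndarray | None = None,
) -> ClusterResult:
    """Cluster permutation test on per-participant difference timecourses.

    ``diffs`` is (participants, time): condition differences for a paired
    contrast, or scores minus chance for a one-sample test.  Each
    permutation independently flips the sign of each participant's
    timecourse; the maximum positive and |negative| cluster masses are
    recorded per permutation, and an observed cluster is significant when
    its mass exceeds the ``1 - cluster_alpha`` quantile of the
    matching-sign null.  ``tail`` is "two", "pos" (only positive clusters
    tested) or "neg".  With 2^n_participants <= n_perm the exact
    enumeration over all sign patterns replaces random sampling.
    """
    if tail not in ("two", "pos", "neg"):
        raise ValueError(f"tail must be 'two', 'pos' or 'neg', got {tail!r}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    D = np.asarray(diffs, dtype=float)
    n, T = D.shape
    df = n - 1
    t_obs = pointwise_t(D)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    clusters = find_clusters(t_obs, df=df, alpha=alpha, times=times)

    exact = 2**n <= n_perm
    if exact:
        logger.warning("only 2^%d = %d distinct sign patterns; using exact enumeration",
                       n, 2**n)
        bits = np.arange(2**n)
        signs = 1 - 2.0 * ((bits[:, None] >> np.arange(n)[None, :]) & 1)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))

    # t for every permutation from sufficient statistics: per-timepoint
    # sum of squares is sign-invariant, only the mean changes.
    sumsq = np.sum(D**2, axis=0)                       # (T,)
    m = signs @ D / n                                  # (R, T)
    var = (sumsq[None, :] - n * m**2) / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        T_perm = np.where(var > 0, m / np.sqrt(var / n), 0.0)
    null_pos, null_neg = _max_cluster_masses(T_perm, tcrit)

    return _assemble_result(clusters, null_pos, null_neg, cluster_alpha, tail,
                            signs.shape[0], seed, exact, t_obs, float(tcrit))


def _assemble_result(clusters, null_pos, null_neg, cluster_alpha, tail,
                     n_permutations, seed, exact, t_obs, tcrit) -> ClusterResult:
    thr_pos = float(np.quantile(null_pos, 1 - cluster_alpha))
    thr_neg = float(np.quantile(null_neg, 1 - cluster_alpha))
    for c in clusters:
        if c.sign > 0:
            c.p = float((null_pos >= c.mass).mean())
            c.significant = tail in ("two", "pos") and c.mass > thr_pos
        else:
            c.p = float((null_neg >= -c.mass).mean())
            c.significant = tail in ("two", "neg") and -c.mass > thr_neg
    return ClusterResult(
        clusters=clusters,
        null_pos=null_pos,
        null_neg=null_neg,
        threshold_pos=thr_pos,
        threshold_neg=thr_neg,
        n_permutations=n_permutations,
        seed=seed,
        exact=exact,
        t_series=t_obs,
        t_critical=tcrit,
    )


def bank_permutation_null(
    observed: np.ndarray,
    banks: np.ndarray,
    n_perm: int = 5000,
    seed: int | None = 0,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    tail: str = "pos",
    times: np.ndarray | None = None,
) -> ClusterResult:
    """Cluster test against a label-permutation null built from per-
    participant banks of permuted-decoding timecourses.

    ``observed`` is (participants, time) -- e.g. decoding accuracy;
    ``banks`` is (participants, n_bank, time) holding, for each
    participant, timecourses recomputed after shuffling that participant's
    trial labels (see ``encoding.permuted_accuracy_bank``).  Each group
    permutation draws one bank entry per participant and recomputes the
    group t and its maximum cluster masses, simulating the global null
    "no location information in any participant" without assuming the
    per-participant statistic is symmetric (cross-validated accuracy at
    chance is not).  Observed clusters are significant when their mass
    exceeds the ``1 - cluster_alpha`` quantile of the matching-sign null;
    the default ``tail='pos'`` tests only above-chance decoding.
    """
    if tail not in ("two", "pos", "neg"):
        raise ValueError(f"tail must be 'two', 'pos' or 'neg', got {tail!r}")
    obs = np.asarray(observed, dtype=float)
    B = np.asarray(banks, dtype=float)
    n, T = obs.shape
    if B.shape[0] != n or B.shape[2] != T:
        raise ValueError(f"banks shape {B.shape} does not match observed {obs.shape}")
    df = n - 1
    tcrit = float(stats.t.ppf(1 - alpha / 2, df))
    t_obs = pointwise_t(obs)
    clusters = find_clusters(t_obs, df=df, alpha=alpha, times=times)

    rng = np.random.default_rng(seed)
    picks = rng.integers(0, B.shape[1], size=(n_perm, n))
    # draws[r] = stack of one bank row per participant
    draws = B[np.arange(n)[None, :], picks]            # (n_perm, n, T)
    m = draws.mean(axis=1)
    var = draws.var(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        T_perm = np.where(var > 0, m / np.sqrt(var / n), 0.0)
    null_pos, null_neg = _max_cluster_masses(T_perm, tcrit)
    return _assemble_result(clusters, null_pos, null_neg, cluster_alpha, tail,
                            n_perm, seed, False, t_obs, tcrit)
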