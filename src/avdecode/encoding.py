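"""Inverted encoding model (IEM) for spatial decoding of multichannel epochs.

The forward model assumes that the sensor pattern evoked by a stimulus at
location ``theta`` is a linear combination of five idealised location
channels:

    B = W C + E

with ``B`` the sensor data (m sensors x n presentations, one matrix per
timepoint), ``C`` the hypothesised channel activities (5 x n), ``W`` the
sensor-by-channel weight matrix, and ``E`` residual noise.  Each channel's
tuning curve is a half-wave rectified sinusoid raised to the fifth power,
with channel centres evenly spaced over the stimulus range.  Weights are
estimated by least squares; the decoder inverts the model taking the residual
noise covariance into account (generalised least squares):

    D = (W' S^-1 W)^-1 W' S^-1

where ``S`` is a shrinkage estimate of the sensor noise covariance.  Applying
``D`` to held-out sensor data reconstructs the channel activity profile, from
which the stimulus location can be read out.  Reconstruction is performed
per timepoint under stratified 10-fold cross-validation so every trial is
decoded by a model that never saw it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChannelBasis",
    "EncodingModel",
    "Reconstruction",
    "basis_response",
    "design_matrix",
    "fit_forward",
    "estimate_noise_cov",
    "invert_model",
    "stratified_folds",
    "cross_validated_reconstruct",
    "per_sensor_information",
]


class SingularDesignError(ValueError):
    """The channel design matrix is rank deficient."""


@dataclass(frozen=True)
class ChannelBasis:
    """Bank of idealised location-tuned channels.

    Parameters
    ----------
    centres : ndarray
        Preferred locations in degrees, strictly increasing; default five
        channels evenly spaced over [-15, +15].
    exponent : int
        Power applied to the rectified sinusoid (default 5).
    period_deg : float
        Spatial wavelength of the underlying sinusoid in degrees.  The
        default of 60 deg gives each channel a half-wave support of 30 deg,
        spanning the stimulus range.
    """

    centres: np.ndarray = field(
        default_factory=lambda: np.linspace(-15.0, 15.0, 5)
    )
    exponent: int = 5
    period_deg: float = 60.0

    def __post_init__(self) -> None:
        c = np.asarray(self.centres, dtype=float)
        object.__setattr__(self, "centres", c)
        if c.ndim != 1 or c.size < 2 or not np.all(np.diff(c) > 0):
            raise ValueError("centres must be a strictly increasing 1-D array")
        if self.period_deg <= 0:
            raise ValueError("period_deg must be > 0")

    @property
    def n_channels(self) -> int:
        return self.centres.size


def basis_response(basis: ChannelBasis, location_deg) -> np.ndarray:
    """Channel responses at one or more stimulus locations.

    Component k is ``max(0, cos(2 pi (location - centre_k) / period)) ** p``.
    Returns shape ``(n_channels,)`` for scalar input, else
    ``(n_channels, n_locations)``.
    """
    loc = np.asarray(location_deg, dtype=float)
    delta = loc[None, ...] - basis.centres.reshape((-1,) + (1,) * loc.ndim)
    resp = np.maximum(0.0, np.cos(2 * np.pi * delta / basis.period_deg)) ** basis.exponent
    return resp


def design_matrix(basis: ChannelBasis, locations) -> np.ndarray:
    """Channel design matrix C (n_channels x n presentations)."""
    locations = np.atleast_1d(np.asarray(locations, dtype=float))
    return basis_response(basis, locations)


def fit_forward(B: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Least-squares forward weights W = B C' (C C')^-1.

    ``B`` is sensors x n (or timepoints x sensors x n for a batched fit);
    ``C`` is channels x n.  Raises :class:`SingularDesignError` when the
    design is rank deficient (e.g. a location never occurs and the basis has
    compact support).
    """
    C = np.asarray(C, dtype=float)
    if np.linalg.matrix_rank(C) < C.shape[0]:
        missing = np.flatnonzero(np.all(np.abs(C) < 1e-12, axis=1))
        raise SingularDesignError(
            f"design matrix rank {np.linalg.matrix_rank(C)} < {C.shape[0]}"
            + (f"; channels {missing.tolist()} receive no stimulation" if missing.size else "")
        )
    gram_inv = np.linalg.inv(C @ C.T)
    return np.asarray(B) @ C.T @ gram_inv


def estimate_noise_cov(E: np.ndarray, shrinkage: float | None = None) -> np.ndarray:
    """Shrinkage covariance of residuals, shrunk toward its diagonal.

    ``Sigma = (1 - lam) S + lam diag(S)`` with ``S`` the sample covariance of
    ``E`` (sensors x n, batched leading axes allowed).  When ``shrinkage`` is
    None the off-diagonal shrinkage intensity is chosen by the analytic
    (Schafer-Strimmer) rule ``lam* = sum Var(s_ij) / sum s_ij^2`` over
    off-diagonal entries, clipped to [0, 1]; this keeps Sigma positive
    definite even when n < sensors.  Zero-variance sensors get a small ridge.
    """
    E = np.asarray(E, dtype=float)
    n = E.shape[-1]
    if n < 2:
        raise ValueError("need at least 2 residual columns to estimate covariance")
    Ec = E - E.mean(axis=-1, keepdims=True)
    S = Ec @ np.swapaxes(Ec, -1, -2) / (n - 1)
    idx = np.arange(S.shape[-1])
    if shrinkage is None:
        # Schafer-Strimmer intensity without materialising the (s, s, n)
        # tensor of per-sample outer products w_ijn = x_in x_jn:
        #   sum_ij sum_n w_ijn^2 = sum_n (sum_i x_in^2)^2
        #   sum_ij wbar_ij^2     = ||Xc Xc' / n||_F^2
        wbar = Ec @ np.swapaxes(Ec, -1, -2) / n
        q = np.sum(Ec**2, axis=-2)                            # (..., n)
        ss_all = np.sum(q**2, axis=-1) - n * np.sum(wbar**2, axis=(-2, -1))
        # diagonal part: sum_i sum_n (x_in^2 - wbar_ii)^2
        x2 = Ec**2
        ss_diag = np.sum(np.sum(x2**2, axis=-1) - n * (wbar[..., idx, idx] ** 2), axis=-1)
        num = n / (n - 1) ** 3 * (ss_all - ss_diag)
        den = np.sum(S**2, axis=(-2, -1)) - np.sum(S[..., idx, idx] ** 2, axis=-1)
        lam = np.where(den > 0, np.clip(num / np.maximum(den, 1e-300), 0.0, 1.0), 1.0)
    else:
        lam = np.clip(float(shrinkage), 0.0, 1.0)
    lam = np.asarray(lam)[..., None, None]
    diag_S = np.zeros_like(S)
    diag_S[..., idx, idx] = S[..., idx, idx]
    Sigma = (1.0 - lam) * S + lam * diag_S
    # guard against exactly-zero-variance sensors
    d = Sigma[..., idx, idx]
    eps = 1e-10 * np.maximum(d.max(axis=-1, keepdims=True), 1.0)
    Sigma[..., idx, idx] = d + eps
    return Sigma


def invert_model(W: np.ndarray, Sigma: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Noise-covariance-aware decoder D = (W' S^-1 W)^-1 W' S^-1.

    Batched leading axes are supported; with ``Sigma`` proportional to the
    identity this reduces to the Moore-Penrose pseudoinverse of ``W``.
    ``ridge`` adds a relative Tikhonov term ``ridge * tr(W'S^-1W)/k * I``
    before inversion, for decoders whose weight matrix is inherently
    ill-conditioned (e.g. single-sensor models).
    """
    W = np.asarray(W, dtype=float)
    if np.any(np.linalg.matrix_rank(W) < W.shape[-1]):
        raise ValueError("weight matrix W is rank deficient; cannot invert")
    Wt = np.swapaxes(W, -1, -2)
    SinvW = np.linalg.solve(Sigma, W)
    A = Wt @ SinvW
    if ridge > 0:
        k = A.shape[-1]
        tr = np.trace(A, axis1=-2, axis2=-1)[..., None, None]
        A = A + ridge * tr / k * np.eye(k)
    return np.linalg.solve(A, np.swapaxes(SinvW, -1, -2))


@dataclass
class EncodingModel:
    """Fitted forward/inverse model for one fold (all timepoints batched)."""

    W: np.ndarray       # (time, sensors, channels)
    Sigma: np.ndarray   # (time, sensors, sensors)
    D: np.ndarray       # (time, channels, sensors)
    fold: int


@dataclass
class Reconstruction:
    """Cross-validated channel reconstructions.

    ``activities`` has shape (trials, channels, time); label arrays are
    aligned with the trial axis of the source epochs.
    """

    activities: np.ndarray
    locations: np.ndarray
    times: np.ndarray
    basis: ChannelBasis
    fold_of_trial: np.ndarray | None = None


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Fold assignment (0..k-1 per trial), stratified by label, seeded.

    Raises ValueError when any stratum holds fewer than ``k`` trials.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds = np.empty(labels.shape[0], dtype=int)
    for val in np.unique(labels):
        idx = np.flatnonzero(labels == val)
        if idx.size < k:
            raise ValueError(
                f"stratum {val!r} has {idx.size} trials < {k} folds; use a smaller k"
            )
        perm = rng.permutation(idx.size)
        folds[idx[perm]] = np.arange(idx.size) % k
    return folds


def _fit_fold(B_train: np.ndarray, C_train: np.ndarray, fold: int,
              ridge: float = 0.0) -> EncodingModel:
    """Fit forward weights, noise covariance and decoder for all timepoints.

    ``B_train``: (n_train, sensors, time); ``C_train``: (channels, n_train).
    """
    # W_t = B_t C' (C C')^-1, batched over time
    gram_inv = np.linalg.inv(C_train @ C_train.T)
    P = C_train.T @ gram_inv                      # (n, channels)
    Bt = np.transpose(B_train, (2, 1, 0))         # (time, sensors, n)
    W = Bt @ P                                    # (time, sensors, channels)
    E = Bt - W @ C_train                          # residuals per timepoint
    Sigma = estimate_noise_cov(E)
    D = invert_model(W, Sigma, ridge=ridge)
    return EncodingModel(W=W, Sigma=Sigma, D=D, fold=fold)


def cross_validated_reconstruct(
    data: np.ndarray,
    locations: np.ndarray,
    times: np.ndarray,
    basis: ChannelBasis | None = None,
    k: int = 10,
    seed: int = 0,
) -> Reconstruction:
    """Decode every trial with a model fit on the other k-1 folds.

    Parameters
    ----------
    data : ndarray, (trials, sensors, time)
        Epoched sensor data.
    locations : ndarray, (trials,)
        Stimulus location per trial, degrees.
    times : ndarray, (time,)
        Epoch time axis, seconds.
    basis : ChannelBasis
        Channel bank (default 5 channels over [-15, 15]).
    k : int
        Number of folds, stratified by location.
    seed : int
        Seed for the stratified fold assignment.

    Models are fit independently at every timepoint (training and testing on
    the same timepoint).
    """
    basis = basis or ChannelBasis()
    data = np.asarray(data, dtype=float)
    locations = np.asarray(locations, dtype=float)
    if data.shape[0] != locations.shape[0]:
        raise ValueError("data and locations disagree on trial count")
    folds = stratified_folds(locations, k=k, seed=seed)
    C_all = design_matrix(basis, locations)      # (channels, trials)
    n_trials, _, n_time = data.shape
    recon = np.empty((n_trials, basis.n_channels, n_time))
    for f in range(k):
        test = folds == f
        train = ~test
        if np.linalg.matrix_rank(C_all[:, train]) < basis.n_channels:
            raise SingularDesignError(f"fold {f}: training design is rank deficient")
        model = _fit_fold(data[train], C_all[:, train], fold=f)
        Btest = np.transpose(data[test], (2, 1, 0))   # (time, sensors, n_test)
        Z = model.D @ Btest                           # (time, channels, n_test)
        recon[test] = np.transpose(Z, (2, 1, 0))
    return Reconstruction(
        activities=recon,
        locations=locations,
        times=np.asarray(times, dtype=float),
        basis=basis,
        fold_of_trial=folds,
    )


def permuted_accuracy_bank(
    data: np.ndarray,
    locations: np.ndarray,
    times: np.ndarray,
    n_perm: int,
    basis: ChannelBasis | None = None,
    k: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Null accuracy timecourses from location-label permutations.

    For each of ``n_perm`` permutations the trial labels are shuffled and
    the full cross-validated reconstruction plus accuracy scoring is re-run,
    giving the exact within-participant null distribution of the accuracy
    timecourse under "no location information".  Returns (n_perm, time).
    Used to build the group-level permutation null for decoding-vs-chance
    tests (cross-validated accuracy at chance is skewed, so sign-flipping
    is not a valid surrogate for this null).
    """
    from .metrics import accuracy_score  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    locations = np.asarray(locations, dtype=float)
    out = np.empty((n_perm, np.asarray(times).size))
    for j in range(n_perm):
        perm = rng.permutation(locations.size)
        locs_j = locations[perm]
        recon = cross_validated_reconstruct(
            data, locs_j, times, basis=basis, k=k,
            seed=int(rng.integers(2**31)),
        )
        out[j] = accuracy_score(recon)
    return out


def per_sensor_information(
    data: np.ndarray,
    locations: np.ndarray,
    times: np.ndarray,
    window_s: tuple[float, float] = (0.15, 0.25),
    basis: ChannelBasis | None = None,
    k: int = 10,
    seed: int = 0,
    ridge: float = 10.0,
) -> np.ndarray:
    """Decoding accuracy per sensor, using time samples as features.

    For each sensor, an inverse model is fit on that sensor's samples within
    ``window_s`` (features = timepoints) under the same stratified CV, and
    the mean accuracy score over trials is returned -- a map of how much
    location information each sensor carries.  A single sensor's weight
    matrix is rank one in channel space in expectation (one tuning profile
    times one temporal kernel), so the unregularised inversion only
    amplifies noise; the default heavy ridge puts the decoder in the
    matched-filter regime, whose expected score is a bounded quadratic form
    in the sensor's tuning weights.
    """
    from .metrics import accuracy_score  # local import to avoid a cycle

    basis = basis or ChannelBasis()
    times = np.asarray(times, dtype=float)
    sel = (times >= window_s[0]) & (times < window_s[1])
    if not np.any(sel):
        raise ValueError(f"window {window_s} lies outside the epoch time axis")
    data = np.asarray(data, dtype=float)[:, :, sel]
    n_trials, n_sensors, n_feat = data.shape
    folds = stratified_folds(np.asarray(locations), k=k, seed=seed)
    C_all = design_matrix(basis, locations)
    scores = np.empty(n_sensors)
    for s in range(n_sensors):
        # (trials, features) treated as a single "timepoint" with features=sensors
        X = data[:, s, :][:, :, None]                 # (trials, features, 1)
        recon = np.empty((n_trials, basis.n_channels))
        for f in range(k):
            test = folds == f
            model = _fit_fold(X[~test], C_all[:, ~test], fold=f, ridge=ridge)
            Z = model.D[0] @ X[test, :, 0].T
            recon[test] = Z.T
        acc = accuracy_score(recon[:, :, None], np.asarray(locations), basis)
        scores[s] = acc[0]
    return scores
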