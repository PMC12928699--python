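"""Synthetic sessions: schedules, MLE-observer behaviour, gaze, and epochs.

This module generates fully synthetic versions of both study sessions so
that every downstream stage (preprocessing, ERP analysis, inverted encoding,
fusion contrasts, behavioural statistics) has a ground-truth surface for
parameter-recovery testing:

* **Schedules** -- the EEG session presents, per condition (auditory A,
  visual V, audiovisual AV), 12 blocks x 10 trials x 20 stimulus
  presentations = 2400 presentations drawn uniformly from five azimuths
  {-15, -7.5, 0, 7.5, 15} degrees; the behavioural session presents, per
  condition, 384 two-interval forced-choice (2IFC) trials with a central
  reference and a target at one of eight azimuths evenly spaced over
  [-15, 15], 48 per location.
* **Observer** -- behavioural responses come from a maximum-likelihood
  (MLE) observer whose single-stimulus location estimate is
  ``theta + N(0, sigma_m^2)`` with the audiovisual noise given by
  reliability-weighted fusion: ``sigma_AV^2 = sigma_A^2 sigma_V^2 /
  (sigma_A^2 + sigma_V^2)``.
* **Epochs** -- each presentation evokes (i) a location-tuned component
  carried by smooth random sensor-loading matrices fixed per participant:
  the auditory and visual modalities project through distinct loadings
  ``M_A`` and ``M_V`` (auditory location information sits in different
  sensors than visual, as on a real scalp), so the audiovisual tuned
  signal is ``(gA M_A + gV M_V + gamma M_int) c(theta) a(t)`` with ``c``
  the channel basis response, ``a`` a Gaussian temporal kernel peaking at
  the information latency, and ``M_int = (M_A + M_V)/2`` the interaction
  topography.  ``gamma`` is the non-linear audiovisual interaction;
  gamma = 0 makes the AV tuned signal exactly the sum of the A and V
  tuned signals; (ii) an untuned evoked component identical across
  locations peaking earlier (the ERP); and (iii) spatially correlated
  Gaussian sensor noise, optionally AR(1) in time.
* **Gaze** -- fixation jitter plus optional saccade excursions, to exercise
  the eye-movement trial-exclusion rule.

All randomness derives from a single seed via ``numpy`` seed sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import ChannelBasis, basis_response
from .io import EpochSet

__all__ = [
    "EEG_LOCATIONS_DEG",
    "ObserverParams",
    "SimConfig",
    "behavioural_locations",
    "make_eeg_schedule",
    "make_behavioural_schedule",
    "simulate_behavioural_responses",
    "simulate_epochs",
    "simulate_gaze",
    "GroundTruth",
]

CONDITIONS = ("A", "V", "AV")
#: The five EEG-session stimulus azimuths, degrees of visual angle.
EEG_LOCATIONS_DEG = np.array([-15.0, -7.5, 0.0, 7.5, 15.0])


def behavioural_locations(n: int = 8) -> np.ndarray:
    """Evenly spaced behavioural-session target azimuths over [-15, 15]."""
    return np.linspace(-15.0, 15.0, n)


@dataclass(frozen=True)
class ObserverParams:
    """MLE-observer parameters.

    ``sigma_a``/``sigma_v`` are the single-stimulus localisation noise SDs
    in degrees for the auditory and visual modalities; the audiovisual SD
    follows from reliability-weighted fusion.  ``lapse`` is the probability
    of a uniform guess.
    """

    sigma_a: float = 13.0
    sigma_v: float = 20.0
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_a <= 0 or self.sigma_v <= 0:
            raise ValueError("sigmas must be > 0")
        if not 0 <= self.lapse < 0.5:
            raise ValueError("lapse must be in [0, 0.5)")

    def sigma(self, condition: str) -> float:
        if condition == "A":
            return self.sigma_a
        if condition == "V":
            return self.sigma_v
        if condition == "AV":
            return float(
                np.sqrt(
                    self.sigma_a**2 * self.sigma_v**2 / (self.sigma_a**2 + self.sigma_v**2)
                )
            )
        raise ValueError(f"unknown condition {condition!r}")


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth generative parameters for synthetic epochs.

    Defaults mirror the study conditions: 64 sensors, 512 Hz epochs from
    -100 to 500 ms, five stimulus azimuths, tuned information peaking at
    180 ms and an untuned evoked component peaking at 100 ms.  ``gamma`` is
    the extra tuned audiovisual gain beyond gA + gV (0 = exactly additive).
    """

    n_participants: int = 41
    n_sensors: int = 64
    sample_rate_hz: float = 512.0
    epoch_window_s: tuple[float, float] = (-0.1, 0.5)
    basis: ChannelBasis = field(default_factory=ChannelBasis)
    gain_a: float = 1.0
    gain_v: float = 1.0
    gamma: float = 0.0
    evoked_amp_a: float = 1.0
    evoked_amp_v: float = 1.0
    evoked_amp_av: float | None = None  # None -> evoked_amp_a + evoked_amp_v (additive ERP)
    info_latency_s: float = 0.18
    info_width_s: float = 0.03
    evoked_latency_s: float = 0.10
    evoked_width_s: float = 0.02
    noise_sigma: float = 1.0
    noise_spatial_scale: float = 0.2  # correlation length in normalised sensor distance
    noise_ar1: float = 0.0           # temporal AR(1) coefficient, 0 = white
    loading_smoothness: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.gain_a, self.gain_v) < 0:
            raise ValueError("condition gains must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not -1 < self.noise_ar1 < 1:
            raise ValueError("noise_ar1 must lie in (-1, 1)")

    @property
    def evoked_amp_av_effective(self) -> float:
        return (
            self.evoked_amp_a + self.evoked_amp_v
            if self.evoked_amp_av is None
            else self.evoked_amp_av
        )

    def tuned_gain(self, condition: str) -> float:
        return {
            "A": self.gain_a,
            "V": self.gain_v,
            "AV": self.gain_a + self.gain_v + self.gamma,
        }[condition]

    def times(self) -> np.ndarray:
        t0, t1 = self.epoch_window_s
        n = int(np.floor((t1 - t0) * self.sample_rate_hz))
        return t0 + np.arange(n) / self.sample_rate_hz


@dataclass
class GroundTruth:
    """Generative parameters returned alongside simulated epochs."""

    loading: dict          # participant -> {"A": M_A, "V": M_V} (sensors, channels)
    evoked_topo: dict      # participant -> (sensors,) untuned topography
    noise_cov: np.ndarray  # (sensors, sensors)
    gains: dict            # condition -> tuned gain
    gamma: float
    config: SimConfig
    seed: int


# ---------------------------------------------------------------------------
# schedules


def make_eeg_schedule(
    n_participants: int = 1,
    n_blocks: int = 12,
    n_trials_per_block: int = 10,
    n_presentations_per_trial: int = 20,
    locations: np.ndarray = EEG_LOCATIONS_DEG,
    seed: int = 0,
) -> pd.DataFrame:
    """EEG-session schedule: per condition, 12 blocks x 10 trials x 20 stimuli.

    Locations are i.i.d. uniform over the five azimuths.  Returns a tidy
    frame with one row per presentation.
    """
    rng = np.random.default_rng(seed)
    rows = []
    n_per_cond = n_blocks * n_trials_per_block * n_presentations_per_trial
    for p in range(n_participants):
        for cond in CONDITIONS:
            locs = rng.choice(locations, size=n_per_cond)
            block = np.repeat(np.arange(n_blocks), n_trials_per_block * n_presentations_per_trial)
            trial = np.tile(
                np.repeat(np.arange(n_trials_per_block), n_presentations_per_trial), n_blocks
            )
            pres = np.tile(np.arange(n_presentations_per_trial), n_blocks * n_trials_per_block)
            rows.append(
                pd.DataFrame(
                    {
                        "participant": p,
                        "condition": cond,
                        "block": block,
                        "trial": trial,
                        "presentation": pres,
                        "location_deg": locs,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def make_behavioural_schedule(
    n_participants: int = 1,
    n_locations: int = 8,
    n_per_location: int = 48,
    seed: int = 0,
) -> pd.DataFrame:
    """Behavioural-session 2IFC schedule: 48 targets per location per condition.

    Each trial holds a central reference and a target at one of the eight
    azimuths; ``target_interval`` (1 or 2) is randomised per trial.
    """
    rng = np.random.default_rng(seed)
    locs = behavioural_locations(n_locations)
    rows = []
    for p in range(n_participants):
        for cond in CONDITIONS:
            target = rng.permutation(np.repeat(locs, n_per_location))
            rows.append(
                pd.DataFrame(
                    {
                        "participant": p,
                        "condition": cond,
                        "trial": np.arange(target.size),
                        "location_deg": target,
                        "target_interval": rng.integers(1, 3, size=target.size),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# observer


def simulate_behavioural_responses(
    schedule: pd.DataFrame, params: ObserverParams, seed: int = 0
) -> pd.DataFrame:
    """2IFC responses of an MLE observer on a behavioural schedule.

    Per trial the observer forms noisy location estimates of the reference
    (at 0 deg) and the target, and reports the interval containing the
    more-leftward estimate.  ``response_rightward`` records whether the
    target was judged right of the reference (the quantity psychometric
    functions are fit to).  With probability ``lapse`` the response is a
    uniform guess.
    """
    rng = np.random.default_rng(seed)
    out = schedule.copy()
    n = len(out)
    sig = out["condition"].map(params.sigma).to_numpy(dtype=float)
    target_est = out["location_deg"].to_numpy(dtype=float) + rng.normal(0, sig)
    ref_est = rng.normal(0, sig)
    judged_right = target_est > ref_est
    lapse_mask = rng.random(n) < params.lapse
    judged_right = np.where(lapse_mask, rng.random(n) < 0.5, judged_right)
    out["response_rightward"] = judged_right
    # interval containing the more-leftward estimate
    tgt_iv = out["target_interval"].to_numpy()
    out["response_interval"] = np.where(judged_right, np.where(tgt_iv == 1, 2, 1), tgt_iv)
    out["correct"] = np.where(
        out["location_deg"] < 0,
        out["response_interval"] == tgt_iv,
        np.where(out["location_deg"] > 0, out["response_interval"] != tgt_iv, np.nan),
    )
    return out


def simulate_eeg_task_responses(
    schedule: pd.DataFrame, params: ObserverParams, seed: int = 0
) -> pd.DataFrame:
    """Left/right-majority judgements for EEG-session stimulus sequences.

    The observer judges the side of each of the 20 stimuli in a sequence
    from its noisy location estimate and responds with the majority side
    (ties in the judgement count resolved at random); with probability
    ``lapse`` the whole-trial response is a uniform guess.  Returns one row
    per sequence with the true side (sign of the location sum; 0 = tie) and
    the response side.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (p, cond, block, trial), grp in schedule.groupby(
        ["participant", "condition", "block", "trial"], sort=True
    ):
        locs = grp["location_deg"].to_numpy(dtype=float)
        sigma = params.sigma(cond)
        est = locs + rng.normal(0, sigma, size=locs.size)
        n_right = int((est > 0).sum())
        n_left = int((est < 0).sum())
        if rng.random() < params.lapse or n_right == n_left:
            resp = int(rng.integers(0, 2)) * 2 - 1
        else:
            resp = 1 if n_right > n_left else -1
        true_right = int((locs > 0).sum())
        true_left = int((locs < 0).sum())
        true_side = int(np.sign(true_right - true_left))
        rows.append(
            {
                "participant": p,
                "condition": cond,
                "block": block,
                "trial": trial,
                "true_side": true_side,
                "response_side": resp,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# epochs


def _smooth_loading(rng: np.random.Generator, n_sensors: int, n_cols: int,
                    scale: float) -> np.ndarray:
    """Random sensor loadings smooth across nominal (1-D) sensor positions."""
    pos = np.linspace(0.0, 1.0, n_sensors)
    K = np.exp(-0.5 * (pos[:, None] - pos[None, :]) ** 2 / scale**2)
    K += 1e-8 * np.eye(n_sensors)
    L = np.linalg.cholesky(K)
    return L @ rng.standard_normal((n_sensors, n_cols))


def noise_covariance(config: SimConfig) -> np.ndarray:
    """Spatially correlated sensor noise covariance (SPD by construction)."""
    pos = np.linspace(0.0, 1.0, config.n_sensors)
    K = np.exp(-0.5 * (pos[:, None] - pos[None, :]) ** 2 / config.noise_spatial_scale**2)
    Sigma = config.noise_sigma**2 * (K + 1e-6 * np.eye(config.n_sensors))
    try:
        np.linalg.cholesky(Sigma + 1e-12 * np.eye(config.n_sensors))
    except np.linalg.LinAlgError as exc:
        raise ValueError("noise covariance is not positive definite") from exc
    return Sigma


def _gauss_kernel(times: np.ndarray, peak: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * (times - peak) ** 2 / width**2)


def simulate_epochs(
    schedule: pd.DataFrame, config: SimConfig
) -> tuple[EpochSet, GroundTruth]:
    """Simulate multichannel epochs for every presentation in a schedule.

    Per presentation with location ``theta``::

        B(t) = M_cond @ c(theta) * a(t) + e_cond * u * v(t) + noise(t)

    with effective tuned loadings ``M_A' = gA M_A``, ``M_V' = gV M_V`` and
    ``M_AV' = gA M_A + gV M_V + gamma (M_A + M_V)/2``; ``a`` and ``v`` are
    the tuned and untuned temporal kernels, ``u`` the untuned topography,
    all sensor loadings smooth random maps fixed per participant; the noise
    is N(0, Sigma) per sample (optionally AR(1) over time).  With gamma = 0
    the AV tuned signal equals the sum of the A and V tuned signals
    exactly.  Identical seeds yield bit-identical output.
    """
    times = config.times()
    n_time = times.size
    if config.noise_sigma > 0:
        Sigma = noise_covariance(config)
        chol = np.linalg.cholesky(Sigma)
    else:
        Sigma = np.zeros((config.n_sensors, config.n_sensors))
        chol = None
    a_t = _gauss_kernel(times, config.info_latency_s, config.info_width_s)
    v_t = _gauss_kernel(times, config.evoked_latency_s, config.evoked_width_s)
    evoked_amp = {
        "A": config.evoked_amp_a,
        "V": config.evoked_amp_v,
        "AV": config.evoked_amp_av_effective,
    }
    root = np.random.SeedSequence(config.seed)
    common_seq, part_root = root.spawn(2)
    # the untuned evoked topography models a cortical generator common to
    # the cohort: shared across participants (plus nothing individual), so
    # group-level ERP statistics behave like grand averages
    rng_common = np.random.default_rng(common_seq)
    u = _smooth_loading(rng_common, config.n_sensors, 1, config.loading_smoothness)[:, 0]
    participants = np.sort(schedule["participant"].unique())
    part_seqs = {p: s for p, s in zip(participants, part_root.spawn(len(participants)))}
    loading: dict = {}
    evoked_topo: dict = {}
    data = np.empty((len(schedule), config.n_sensors, n_time))
    labels = schedule.reset_index(drop=True).copy()
    order = labels.index.to_numpy()
    for p in participants:
        seqs = part_seqs[p].spawn(2)
        rng_struct = np.random.default_rng(seqs[0])
        rng_noise = np.random.default_rng(seqs[1])
        M_A = _smooth_loading(rng_struct, config.n_sensors, config.basis.n_channels,
                              config.loading_smoothness)
        M_V = _smooth_loading(rng_struct, config.n_sensors, config.basis.n_channels,
                              config.loading_smoothness)
        M_eff = {
            "A": config.gain_a * M_A,
            "V": config.gain_v * M_V,
            "AV": config.gain_a * M_A + config.gain_v * M_V
            + config.gamma * 0.5 * (M_A + M_V),
        }
        loading[int(p)] = {"A": M_A, "V": M_V}
        evoked_topo[int(p)] = u
        mask = (labels["participant"] == p).to_numpy()
        idx = order[mask]
        locs = labels.loc[mask, "location_deg"].to_numpy(dtype=float)
        conds = labels.loc[mask, "condition"].to_numpy()
        C = basis_response(config.basis, locs)                 # (channels, n_p)
        e = np.array([evoked_amp[c] for c in conds])
        tuned_topo = np.empty((idx.size, config.n_sensors))
        for cond in CONDITIONS:
            cmask = conds == cond
            if cmask.any():
                tuned_topo[cmask] = (M_eff[cond] @ C[:, cmask]).T
        signal = (
            tuned_topo[:, :, None] * a_t[None, None, :]
            + (e[:, None] * u[None, :])[:, :, None] * v_t[None, None, :]
        )
        if config.noise_sigma > 0:
            white = rng_noise.standard_normal((idx.size, config.n_sensors, n_time))
            if config.noise_ar1 != 0.0:
                phi = config.noise_ar1
                ar = np.empty_like(white)
                ar[:, :, 0] = white[:, :, 0]
                for t in range(1, n_time):
                    ar[:, :, t] = phi * ar[:, :, t - 1] + np.sqrt(1 - phi**2) * white[:, :, t]
                white = ar
            noise = np.einsum("ij,njt->nit", chol, white)
            signal = signal + noise
        data[idx] = signal
    epochs = EpochSet(
        data=data,
        times=times,
        sample_rate=config.sample_rate_hz,
        labels=labels,
        meta={"generator": "avdecode.synthetic", "seed": config.seed,
              "gamma": config.gamma},
    )
    truth = GroundTruth(
        loading=loading,
        evoked_topo=evoked_topo,
        noise_cov=Sigma,
        gains={c: config.tuned_gain(c) for c in CONDITIONS},
        gamma=config.gamma,
        config=config,
        seed=config.seed,
    )
    return epochs, truth


# ---------------------------------------------------------------------------
# gaze


def simulate_gaze(
    schedule: pd.DataFrame,
    n_samples: int,
    saccade_prob: float = 0.0,
    saccade_amp_deg: float = 5.0,
    jitter_sd_deg: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Per-presentation 2-D gaze traces, degrees from fixation.

    Returns an array of shape (n_presentations, 2, n_samples).  A fraction
    ``saccade_prob`` of presentations contains a horizontal excursion of
    amplitude ``saccade_amp_deg`` starting at a random sample and lasting to
    the end of the epoch; all traces carry Gaussian fixation jitter with SD
    ``jitter_sd_deg``.
    """
    rng = np.random.default_rng(seed)
    n = len(schedule)
    gaze = rng.normal(0.0, jitter_sd_deg, size=(n, 2, n_samples))
    saccade = rng.random(n) < saccade_prob
    for i in np.flatnonzero(saccade):
        onset = rng.integers(0, max(1, n_samples - 1))
        direction = 1 if rng.random() < 0.5 else -1
        gaze[i, 0, onset:] += direction * saccade_amp_deg
    return gaze
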