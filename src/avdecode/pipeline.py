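"""Pipeline driver: chains every stage of the synthetic experiment.

``run_pipeline`` executes simulate -> preprocess -> ERP -> decode (A, V,
AV, aggregate) -> fusion contrasts -> behaviour -> decoding-vs-chance
statistics -> report, writing tidy CSV / JSON outputs plus a manifest into
a results directory.  Each stage is independently invocable (the CLI maps
one subcommand to each) and reads its inputs from the same directory, so a
partial pipeline can be resumed or re-run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behaviour import (
    behavioural_dprime,
    fit_psychometric,
    mle_predicted_slope,
    neurobehavioural_correlation,
    wilcoxon_signed_rank,
)
from .cluster import bank_permutation_null, permutation_null
from .encoding import ChannelBasis, cross_validated_reconstruct, permuted_accuracy_bank
from .erp import additive_contrast, erp_by_condition
from .fusion import build_aggregate, mle_dprime, superadditivity_contrast
from .io import read_epochs, write_epochs
from .metrics import accuracy_score, decoder_dprime, location_estimate
from .preprocessing import exclude_eye_trials, rereference_average
from .synthetic import (
    CONDITIONS,
    ObserverParams,
    SimConfig,
    make_behavioural_schedule,
    make_eeg_schedule,
    simulate_behavioural_responses,
    simulate_eeg_task_responses,
    simulate_epochs,
    simulate_gaze,
)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES", "run_stage",
           "simulate_cohort_dprimes"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


_ALLOWED = {
    "seed": None,
    "simulation": {
        "n_participants", "n_sensors", "sample_rate_hz", "epoch_window_s",
        "gain_a", "gain_v", "gamma", "evoked_amp_a", "evoked_amp_v", "evoked_amp_av",
        "info_latency_s", "info_width_s", "evoked_latency_s", "evoked_width_s",
        "noise_sigma", "noise_spatial_scale", "noise_ar1", "loading_smoothness",
        "n_blocks", "n_trials_per_block", "n_presentations_per_trial",
    },
    "preprocessing": {"eye_threshold_deg", "saccade_prob", "saccade_amp_deg"},
    "encoding": {"folds", "basis_period_deg", "basis_exponent"},
    "stats": {"n_perm", "alpha"},
    "behaviour": {"sigma_a", "sigma_v", "lapse"},
}


@dataclass
class PipelineConfig:
    """Validated configuration for the full synthetic experiment."""

    seed: int
    simulation: dict = field(default_factory=dict)
    preprocessing: dict = field(default_factory=dict)
    encoding: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    behaviour: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        if "seed" not in d:
            raise ConfigError("missing required key 'seed'")
        unknown_top = set(d) - set(_ALLOWED)
        if unknown_top:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown_top)}")
        for block, allowed in _ALLOWED.items():
            if allowed is None or block not in d:
                continue
            unknown = set(d[block]) - allowed
            if unknown:
                raise ConfigError(f"unknown key(s) in '{block}': {sorted(unknown)}")
        return cls(
            seed=int(d["seed"]),
            simulation=dict(d.get("simulation", {})),
            preprocessing=dict(d.get("preprocessing", {})),
            encoding=dict(d.get("encoding", {})),
            stats=dict(d.get("stats", {})),
            behaviour=dict(d.get("behaviour", {})),
        )

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(json.load(f))

    def sim_config(self) -> SimConfig:
        sim = {k: v for k, v in self.simulation.items()
               if k not in ("n_blocks", "n_trials_per_block", "n_presentations_per_trial")}
        if "epoch_window_s" in sim:
            sim["epoch_window_s"] = tuple(sim["epoch_window_s"])
        enc = self.encoding
        basis = ChannelBasis(
            period_deg=enc.get("basis_period_deg", 60.0),
            exponent=enc.get("basis_exponent", 5),
        )
        return SimConfig(basis=basis, seed=self.seed, **sim)


def simulate_cohort_dprimes(
    n_participants: int = 24,
    sim_kwargs: dict | None = None,
    n_blocks: int = 2,
    n_trials_per_block: int = 10,
    n_presentations_per_trial: int = 10,
    k: int = 5,
    seed: int = 0,
    metric: str = "dprime",
) -> tuple[dict, np.ndarray]:
    """One in-memory synthetic experiment: per-participant decoding timecourses.

    Simulates a cohort (each participant gets an independent schedule,
    loading matrices and noise), decodes the three conditions plus the
    sensor-concatenated aggregate with cross-validated inverted encoding,
    and returns ``{"A"|"V"|"AV"|"AGG": (participants, time) array}`` of the
    requested metric ("dprime" or "accuracy") plus the epoch time axis.
    This is the fast path behind the calibration analyses; the file-based
    pipeline produces the same quantities via :func:`run_pipeline`.
    """
    sim_kwargs = dict(sim_kwargs or {})
    conds = ("A", "V", "AV", "AGG")
    out: dict = {c: [] for c in conds}
    times = None
    for ss in np.random.SeedSequence(seed).spawn(n_participants):
        s = int(ss.generate_state(1)[0] % (2**31))
        sim = SimConfig(n_participants=1, seed=s, **sim_kwargs)
        sched = make_eeg_schedule(
            n_participants=1, n_blocks=n_blocks,
            n_trials_per_block=n_trials_per_block,
            n_presentations_per_trial=n_presentations_per_trial, seed=s,
        )
        epochs, _ = simulate_epochs(sched, sim)
        times = epochs.times
        sets = {c: epochs.select((epochs.labels["condition"] == c).to_numpy())
                for c in CONDITIONS}
        sets["AGG"] = build_aggregate(sets["A"], sets["V"], seed=s + 1)
        for cond in conds:
            eset = sets[cond]
            locs = eset.labels["location_deg"].to_numpy(dtype=float)
            recon = cross_validated_reconstruct(
                eset.data, locs, eset.times, basis=sim.basis, k=k, seed=s + 2
            )
            if metric == "dprime":
                vals = decoder_dprime(location_estimate(recon), locs)
            elif metric == "accuracy":
                vals = accuracy_score(recon)
            else:
                raise ValueError(f"unknown metric {metric!r}")
            out[cond].append(vals)
    return {c: np.asarray(v) for c, v in out.items()}, times


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    sim = cfg.sim_config()
    sched = make_eeg_schedule(
        n_participants=sim.n_participants,
        n_blocks=cfg.simulation.get("n_blocks", 12),
        n_trials_per_block=cfg.simulation.get("n_trials_per_block", 10),
        n_presentations_per_trial=cfg.simulation.get("n_presentations_per_trial", 20),
        seed=cfg.seed,
    )
    sched.to_csv(out / "eeg_schedule.csv", index=False)
    epochs, truth = simulate_epochs(sched, sim)
    write_epochs(epochs, str(out / "epochs_raw.h5"))
    gaze = simulate_gaze(
        sched,
        n_samples=epochs.n_times,
        saccade_prob=cfg.preprocessing.get("saccade_prob", 0.0),
        saccade_amp_deg=cfg.preprocessing.get("saccade_amp_deg", 5.0),
        seed=cfg.seed + 1,
    )
    np.save(out / "gaze.npy", gaze)
    obs = ObserverParams(
        sigma_a=cfg.behaviour.get("sigma_a", 13.0),
        sigma_v=cfg.behaviour.get("sigma_v", 20.0),
        lapse=cfg.behaviour.get("lapse", 0.0),
    )
    bsched = make_behavioural_schedule(n_participants=sim.n_participants, seed=cfg.seed + 2)
    btrials = simulate_behavioural_responses(bsched, obs, seed=cfg.seed + 3)
    btrials.to_csv(out / "behavioural_trials.csv", index=False)
    eeg_task = simulate_eeg_task_responses(sched, obs, seed=cfg.seed + 4)
    eeg_task.to_csv(out / "eeg_task_trials.csv", index=False)
    with open(out / "ground_truth.json", "w") as f:
        json.dump(
            {
                "gains": truth.gains,
                "gamma": truth.gamma,
                "seed": truth.seed,
                "n_participants": sim.n_participants,
            },
            f,
            indent=1,
        )


def stage_preprocess(cfg: PipelineConfig, out: Path) -> None:
    epochs = read_epochs(str(out / "epochs_raw.h5"))
    gaze = np.load(out / "gaze.npy")
    epochs = rereference_average(epochs)
    epochs, report = exclude_eye_trials(
        epochs, gaze, threshold_deg=cfg.preprocessing.get("eye_threshold_deg", 3.75)
    )
    write_epochs(epochs, str(out / "epochs_pre.h5"))
    report.to_csv(out / "exclusion_report.csv", index=False)


def stage_erp(cfg: PipelineConfig, out: Path) -> None:
    epochs = read_epochs(str(out / "epochs_pre.h5"))
    n_perm = cfg.stats.get("n_perm", 5000)
    rows = []
    contrasts = []
    # after average re-referencing the all-sensor mean is identically zero,
    # so ERPs are taken over a sensor subset (back half of the array, the
    # stand-in for the posterior channels carrying the evoked response)
    sensor_subset = np.arange(epochs.n_sensors // 2, epochs.n_sensors)
    for p, grp_idx in epochs.labels.groupby("participant").groups.items():
        sub = epochs.select(np.asarray(grp_idx))
        erps = erp_by_condition(sub, sensors=sensor_subset)
        for cond, tc in erps.items():
            rows.append(pd.DataFrame({
                "participant": p, "condition": cond,
                "time_s": epochs.times, "amplitude": tc,
            }))
        contrasts.append(additive_contrast(erps["A"], erps["V"], erps["AV"]))
    pd.concat(rows, ignore_index=True).to_csv(out / "erp.csv", index=False)
    contrast = np.stack(contrasts)
    pd.DataFrame(contrast, columns=[f"{t:.4f}" for t in epochs.times]).to_csv(
        out / "erp_additive_contrast.csv", index=False
    )
    if contrast.shape[0] >= 3:
        res = permutation_null(contrast, n_perm=n_perm, seed=cfg.seed + 10,
                               times=epochs.times)
        _write_cluster_json(res, out / "erp_additive_clusters.json")


def _write_cluster_json(res, path: Path) -> None:
    with open(path, "w") as f:
        json.dump(
            {
                "n_permutations": res.n_permutations,
                "exact": res.exact,
                "threshold_pos": res.threshold_pos,
                "threshold_neg": res.threshold_neg,
                "clusters": [
                    {
                        "start": c.start, "end": c.end,
                        "start_time_s": c.start_time, "end_time_s": c.end_time,
                        "sign": c.sign, "mass": c.mass, "p": c.p,
                        "significant": c.significant,
                    }
                    for c in res.clusters
                ],
            },
            f,
            indent=1,
        )


def stage_decode(cfg: PipelineConfig, out: Path) -> None:
    epochs = read_epochs(str(out / "epochs_pre.h5")).kept()
    k = cfg.encoding.get("folds", 10)
    basis = ChannelBasis(
        period_deg=cfg.encoding.get("basis_period_deg", 60.0),
        exponent=cfg.encoding.get("basis_exponent", 5),
    )
    rows = []
    participants = np.sort(epochs.labels["participant"].unique())
    for p in participants:
        pmask = (epochs.labels["participant"] == p).to_numpy()
        sub = epochs.select(pmask)
        per_cond = {}
        for cond in CONDITIONS:
            cmask = (sub.labels["condition"] == cond).to_numpy()
            per_cond[cond] = sub.select(cmask)
        per_cond["AGG"] = build_aggregate(per_cond["A"], per_cond["V"],
                                          seed=cfg.seed + 20 + int(p))
        for cond, eset in per_cond.items():
            locs = eset.labels["location_deg"].to_numpy(dtype=float)
            recon = cross_validated_reconstruct(
                eset.data, locs, eset.times, basis=basis, k=k,
                seed=cfg.seed + 30 + int(p),
            )
            acc = accuracy_score(recon)
            est = location_estimate(recon)
            dp = decoder_dprime(est, locs)
            for metric, vals in (("accuracy", acc), ("dprime", dp)):
                rows.append(pd.DataFrame({
                    "participant": p, "condition": cond, "metric": metric,
                    "time_s": epochs.times, "value": vals,
                }))
    pd.concat(rows, ignore_index=True).to_csv(out / "decoding_timecourses.csv", index=False)


def _load_metric(out: Path, metric: str) -> tuple[np.ndarray, dict, np.ndarray]:
    df = pd.read_csv(out / "decoding_timecourses.csv")
    df = df[df["metric"] == metric]
    times = np.sort(df["time_s"].unique())
    participants = np.sort(df["participant"].unique())
    data = {}
    for cond, grp in df.groupby("condition"):
        mat = grp.pivot_table(index="participant", columns="time_s", values="value")
        data[cond] = mat.loc[participants].to_numpy()
    return participants, data, times


def stage_fuse(cfg: PipelineConfig, out: Path) -> None:
    n_perm = cfg.stats.get("n_perm", 5000)
    alpha = cfg.stats.get("alpha", 0.05)
    participants, dp, times = _load_metric(out, "dprime")
    pred_mle = mle_dprime(dp["A"], dp["V"])
    pd.DataFrame(pred_mle, columns=[f"{t:.4f}" for t in times]).to_csv(
        out / "mle_prediction.csv", index=False
    )
    for name, pred in (("mle", pred_mle), ("aggregate", dp["AGG"])):
        diffs, res = superadditivity_contrast(
            dp["AV"], pred, n_perm=n_perm, seed=cfg.seed + 40, alpha=alpha, times=times
        )
        _write_cluster_json(res, out / f"superadditivity_vs_{name}.json")


def stage_behaviour(cfg: PipelineConfig, out: Path) -> None:
    btrials = pd.read_csv(out / "behavioural_trials.csv")
    fits = []
    for (p, cond), grp in btrials.groupby(["participant", "condition"]):
        fit = fit_psychometric(grp["location_deg"], grp["response_rightward"])
        fits.append({"participant": p, "condition": cond, "pse_deg": fit.pse,
                     "sigma_deg": fit.sigma, "slope_per_deg": fit.slope_at_pse})
    fits = pd.DataFrame(fits)
    piv = fits.pivot(index="participant", columns="condition", values="slope_per_deg")
    piv["MLE_pred"] = [mle_predicted_slope(a, v) for a, v in zip(piv["A"], piv["V"])]
    fits.to_csv(out / "psychometric_fits.csv", index=False)
    eeg_task = pd.read_csv(out / "eeg_task_trials.csv")
    dps = []
    for (p, cond), grp in eeg_task.groupby(["participant", "condition"]):
        dps.append({"participant": p, "condition": cond,
                    "dprime": behavioural_dprime(grp)})
    dps = pd.DataFrame(dps)
    dps.to_csv(out / "eeg_task_dprime.csv", index=False)
    stats_out: dict = {}
    if piv.shape[0] >= 5:
        for a, b in (("AV", "A"), ("AV", "V"), ("A", "V"), ("AV", "MLE_pred")):
            z, pval = wilcoxon_signed_rank(piv[a].to_numpy(), piv[b].to_numpy())
            stats_out[f"slope_{a}_vs_{b}"] = {"Z": z, "p": pval}
    with open(out / "behaviour_stats.json", "w") as f:
        json.dump(stats_out, f, indent=1)


def stage_stats(cfg: PipelineConfig, out: Path) -> None:
    """Decoding-accuracy-vs-chance cluster tests plus neurobehavioural rho.

    The null for decoding-vs-chance is built by permuting location labels
    and re-decoding (cross-validated accuracy at chance is skewed, so
    sign-flipping does not reproduce this null).
    """
    n_perm = cfg.stats.get("n_perm", 5000)
    n_bank = 20
    k = cfg.encoding.get("folds", 10)
    basis = ChannelBasis(
        period_deg=cfg.encoding.get("basis_period_deg", 60.0),
        exponent=cfg.encoding.get("basis_exponent", 5),
    )
    participants, acc, times = _load_metric(out, "accuracy")
    epochs = read_epochs(str(out / "epochs_pre.h5")).kept()
    results = {}
    for cond, mat in acc.items():
        if mat.shape[0] < 3 or cond == "AGG":
            continue
        banks = []
        for p in participants:
            mask = ((epochs.labels["participant"] == p)
                    & (epochs.labels["condition"] == cond)).to_numpy()
            sub = epochs.select(mask)
            banks.append(permuted_accuracy_bank(
                sub.data, sub.labels["location_deg"].to_numpy(dtype=float),
                sub.times, n_perm=n_bank, basis=basis, k=k,
                seed=cfg.seed + 60 + int(p),
            ))
        res = bank_permutation_null(mat, np.asarray(banks), n_perm=n_perm,
                                    seed=cfg.seed + 50, times=times)
        _write_cluster_json(res, out / f"decoding_vs_chance_{cond}.json")
        results[cond] = len(res.significant_clusters)
    _, dp, _ = _load_metric(out, "dprime")
    eeg_task = pd.read_csv(out / "eeg_task_dprime.csv")
    corr = {}
    if len(participants) >= 5:
        for cond in CONDITIONS:
            behav = (
                eeg_task[eeg_task["condition"] == cond]
                .set_index("participant")["dprime"]
                .loc[participants]
                .to_numpy()
            )
            rho, pval = neurobehavioural_correlation(dp[cond], times, behav)
            corr[cond] = {"rho": rho, "p": pval}
    with open(out / "neurobehavioural.json", "w") as f:
        json.dump(corr, f, indent=1)


def stage_report(cfg: PipelineConfig, out: Path) -> None:
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "outputs": {
            p.name: _hash_file(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.suffix in (".csv", ".json", ".h5", ".npy")
            and p.name != "manifest.json"
        },
        "generated_unix_time": int(time.time()),
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "erp": stage_erp,
    "decode": stage_decode,
    "fuse": stage_fuse,
    "behaviour": stage_behaviour,
    "stats": stage_stats,
    "report": stage_report,
}


def run_stage(name: str, cfg: PipelineConfig, out_dir: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    try:
        STAGES[name](cfg, out)
    except Exception as exc:
        raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
    logger.info("stage %-10s %6.2f s", name, time.perf_counter() - t0)


def run_pipeline(cfg: PipelineConfig, out_dir: str) -> Path:
    """Run all stages in order; returns the results directory path."""
    for name in STAGES:
        run_stage(name, cfg, out_dir)
    return Path(out_dir)
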