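"""Super-additivity machinery: MLE prediction, aggregate baseline, contrast.

Two linear baselines bound what audiovisual decoding sensitivity should be
if auditory and visual information merely co-exist without interacting:

* the **MLE prediction** ``d'_AV = sqrt(d'_A^2 + d'_V^2)`` -- optimal
  reliability-weighted combination of the two unisensory sensitivities;
* the **aggregate** baseline -- auditory and visual trials matched by
  stimulus location and concatenated along the sensor axis, then decoded
  like a real condition: both unisensory patterns are present but cannot
  interact.

Audiovisual sensitivity exceeding either baseline (one-sided cluster
permutation test) is evidence for super-additive multisensory integration.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .cluster import ClusterResult, permutation_null
from .io import EpochSet

__all__ = ["mle_dprime", "build_aggregate", "superadditivity_contrast"]


def mle_dprime(dprime_a, dprime_v):
    """Predicted optimal audiovisual sensitivity sqrt(d'_A^2 + d'_V^2)."""
    a = np.asarray(dprime_a, dtype=float)
    v = np.asarray(dprime_v, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(v))):
        raise ValueError("d' inputs must be finite")
    return np.sqrt(a**2 + v**2)


def build_aggregate(epochs_a: EpochSet, epochs_v: EpochSet, seed: int = 0) -> EpochSet:
    """Sensor-concatenated 'additive' dataset from matched unisensory trials.

    Within each stimulus location, kept auditory and visual trials are
    randomly paired (seeded; subsampled to the smaller count) and each pair
    is concatenated along the sensor axis, yielding trials with
    ``n_sensors_A + n_sensors_V`` sensors and the shared location label.
    Raises when a location occurs in only one condition.
    """
    a, v = epochs_a.kept(), epochs_v.kept()
    if not np.allclose(a.times, v.times):
        raise ValueError("unisensory epoch sets must share a time axis")
    loc_a = a.labels["location_deg"].to_numpy(dtype=float)
    loc_v = v.labels["location_deg"].to_numpy(dtype=float)
    locs_a, locs_v = set(np.unique(loc_a)), set(np.unique(loc_v))
    if locs_a != locs_v:
        raise ValueError(
            f"location sets differ between conditions: {sorted(locs_a ^ locs_v)}"
        )
    rng = np.random.default_rng(seed)
    pieces, labels = [], []
    for loc in sorted(locs_a):
        ia = np.flatnonzero(np.isclose(loc_a, loc))
        iv = np.flatnonzero(np.isclose(loc_v, loc))
        m = min(ia.size, iv.size)
        ia = rng.permutation(ia)[:m]
        iv = rng.permutation(iv)[:m]
        pieces.append(np.concatenate([a.data[ia], v.data[iv]], axis=1))
        labels.append(
            pd.DataFrame(
                {
                    "participant": a.labels["participant"].to_numpy()[ia]
                    if "participant" in a.labels.columns
                    else 0,
                    "condition": "AGG",
                    "location_deg": loc,
                    "kept": True,
                }
            )
        )
    return EpochSet(
        data=np.concatenate(pieces, axis=0),
        times=a.times,
        sample_rate=a.sample_rate,
        labels=pd.concat(labels, ignore_index=True),
        meta={**a.meta, "aggregate_of": ["A", "V"], "pairing_seed": seed},
    )


def superadditivity_contrast(
    dprime_av: np.ndarray,
    prediction: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
    times: np.ndarray | None = None,
) -> tuple[np.ndarray, ClusterResult]:
    """Paired AV-minus-baseline difference with a one-sided cluster test.

    ``dprime_av`` and ``prediction`` are (participants, time) sensitivity
    timecourses aligned on the same participants; the test is one-sided for
    AV > prediction (the super-additivity hypothesis is directional).
    Returns the per-participant difference array and the cluster result.
    """
    av = np.asarray(dprime_av, dtype=float)
    pred = np.asarray(prediction, dtype=float)
    if av.shape != pred.shape:
        raise ValueError(
            f"participant/time grids differ: {av.shape} vs {pred.shape}"
        )
    diffs = av - pred
    result = permutation_null(diffs, n_perm=n_perm, seed=seed, alpha=alpha,
                              tail="pos", times=times)
    return diffs, result
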