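"""Scalar decoding performance surfaces: accuracy (a.u.) and decoder d'.

Channel reconstructions are turned into two timecourses per participant and
condition:

* **Decoding accuracy** -- the similarity of the reconstructed channel
  profile to the ideal profile of the presented location, in arbitrary
  units.  Each ideal channel vector is mean-centred and unit-normalised;
  the score for a trial is the projection onto the true location's ideal
  vector minus the mean projection onto all locations' ideal vectors, so
  chance level is exactly 0.
* **Decoder sensitivity (d')** -- trials at the display centre are omitted,
  each reconstruction is reduced to a location estimate (rectified centroid
  of the channel profile), estimates are binarised by side, and d' =
  Phi^-1(H) - Phi^-1(F) with hit/false-alarm proportions clipped to
  [1/(2N), 1 - 1/(2N)].
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .encoding import ChannelBasis, Reconstruction, basis_response

__all__ = [
    "ideal_vectors",
    "accuracy_score",
    "location_estimate",
    "decoder_dprime",
    "dprime_from_rates",
]


def ideal_vectors(basis: ChannelBasis, locations: np.ndarray) -> np.ndarray:
    """Centred, unit-normalised ideal channel vectors, one column per location."""
    V = basis_response(basis, np.asarray(locations, dtype=float))  # (channels, L)
    V = V - V.mean(axis=0, keepdims=True)
    nrm = np.linalg.norm(V, axis=0, keepdims=True)
    if np.any(nrm == 0):
        raise ValueError("degenerate ideal vector (constant channel profile)")
    return V / nrm


def accuracy_score(
    recon,
    true_locations: np.ndarray | None = None,
    basis: ChannelBasis | None = None,
    location_set: np.ndarray | None = None,
    per_trial: bool = False,
    similarity: str = "centred",
) -> np.ndarray:
    """Decoding accuracy timecourse in arbitrary units (chance = 0).

    ``recon`` may be a :class:`Reconstruction` or a raw activity array of
    shape (trials, channels, time) with ``true_locations`` and ``basis``
    given explicitly.  ``similarity`` selects the reading of "similarity
    to the presented location": ``"centred"`` (default) projects onto
    centred unit ideal vectors; ``"cosine"`` uses the cosine between the
    reconstruction and the raw ideal vector.  Either way the mean
    similarity over all candidate locations is subtracted, so chance
    stays at 0.  Returns shape (time,), or (trials, time) when
    ``per_trial`` is True.
    """
    if isinstance(recon, Reconstruction):
        Z, loc, basis = recon.activities, recon.locations, recon.basis
    else:
        Z = np.asarray(recon, dtype=float)
        loc = np.asarray(true_locations, dtype=float)
        if basis is None:
            raise ValueError("basis required when passing a raw activity array")
    locset = np.unique(loc) if location_set is None else np.asarray(location_set, float)
    if similarity == "centred":
        V = ideal_vectors(basis, locset)                # (channels, L)
        proj = np.einsum("nct,cl->nlt", Z, V)           # (trials, L, time)
    elif similarity == "cosine":
        V = basis_response(basis, locset)
        V = V / np.linalg.norm(V, axis=0, keepdims=True)
        nrm = np.linalg.norm(Z, axis=1, keepdims=True)
        proj = np.einsum("nct,cl->nlt", Z / np.where(nrm > 0, nrm, 1.0), V)
    else:
        raise ValueError(f"unknown similarity {similarity!r}")
    true_idx = np.searchsorted(locset, loc)
    scores = proj[np.arange(Z.shape[0]), true_idx] - proj.mean(axis=1)
    return scores if per_trial else scores.mean(axis=0)


def location_estimate(recon, basis: ChannelBasis | None = None) -> np.ndarray:
    """Rectified-centroid location estimate, degrees, per trial and timepoint.

    estimate = sum_k centre_k max(0, z_k) / sum_k max(0, z_k); trials where
    every channel activity is <= 0 are degenerate and read out as 0.
    """
    if isinstance(recon, Reconstruction):
        Z, basis = recon.activities, recon.basis
    else:
        Z = np.asarray(recon, dtype=float)
        if basis is None:
            raise ValueError("basis required when passing a raw activity array")
    pos = np.maximum(0.0, Z)                            # (trials, channels, time)
    wsum = pos.sum(axis=1)
    num = np.einsum("nct,c->nt", pos, basis.centres)
    with np.errstate(invalid="ignore", divide="ignore"):
        est = np.where(wsum > 0, num / np.where(wsum > 0, wsum, 1.0), 0.0)
    return est


def dprime_from_rates(hits: float | np.ndarray, fas: float | np.ndarray,
                      n_signal: int, n_noise: int) -> np.ndarray:
    """d' = Phi^-1(H) - Phi^-1(F) with 1/(2N) clipping of extreme proportions."""
    H = np.clip(hits, 1.0 / (2 * n_signal), 1.0 - 1.0 / (2 * n_signal))
    F = np.clip(fas, 1.0 / (2 * n_noise), 1.0 - 1.0 / (2 * n_noise))
    return norm.ppf(H) - norm.ppf(F)


def decoder_dprime(estimates: np.ndarray, true_locations: np.ndarray) -> np.ndarray:
    """Decoder sensitivity timecourse from per-trial location estimates.

    Signal is "right": H = P(est > 0 | loc > 0), F = P(est > 0 | loc < 0).
    Centre-location trials (loc == 0) are omitted.  ``estimates`` has shape
    (trials, time); returns (time,).
    """
    loc = np.asarray(true_locations, dtype=float)
    est = np.asarray(estimates, dtype=float)
    right = loc > 0
    left = loc < 0
    nR, nL = int(right.sum()), int(left.sum())
    if nR == 0 or nL == 0:
        raise ValueError(f"need trials on both sides (right={nR}, left={nL})")
    H = (est[right] > 0).mean(axis=0)
    F = (est[left] > 0).mean(axis=0)
    return dprime_from_rates(H, F, nR, nL)
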