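"""Univariate event-related potentials and the additive (A+V vs AV) contrast.

ERPs are computed by averaging epochs across kept presentations and across
a sensor subset, per participant, condition and stimulus location.  The
additive contrast, (ERP_A + ERP_V) - ERP_AV, tests whether the audiovisual
evoked response exceeds the sum of the unisensory responses; under linear
superposition of independent unisensory generators it is zero.
"""

from __future__ import annotations

import numpy as np

from .io import EpochSet

__all__ = ["compute_erp", "additive_contrast", "erp_by_condition"]


class EmptyCellError(ValueError):
    """No kept trials in the requested condition/location cell."""


def compute_erp(
    epochs: EpochSet,
    condition: str | None = None,
    location_deg: float | None = None,
    sensors: np.ndarray | None = None,
    baseline: bool = True,
) -> np.ndarray:
    """Mean timecourse over kept trials and sensors for one cell.

    ``sensors`` selects a subset (indices); default all.  When ``baseline``
    is True the mean over the pre-stimulus interval (t < 0) is subtracted.
    Raises :class:`EmptyCellError` when no kept trial matches.
    """
    # note: to_numpy() may be a zero-copy view of the label column, so
    # combine masks without in-place ops
    mask = np.array(epochs.labels["kept"], dtype=bool)
    if condition is not None:
        mask = mask & (epochs.labels["condition"] == condition).to_numpy()
    if location_deg is not None:
        mask = mask & np.isclose(
            epochs.labels["location_deg"].to_numpy(dtype=float), location_deg
        )
    if not mask.any():
        raise EmptyCellError(
            f"no kept trials for condition={condition!r}, location={location_deg!r}"
        )
    data = epochs.data[mask]
    if sensors is not None:
        data = data[:, np.asarray(sensors)]
    erp = data.mean(axis=(0, 1))
    if baseline:
        pre = epochs.times < 0
        if pre.any():
            erp = erp - erp[pre].mean()
    return erp


def erp_by_condition(
    epochs: EpochSet,
    conditions=("A", "V", "AV"),
    sensors: np.ndarray | None = None,
    baseline: bool = True,
) -> dict:
    """ERP per condition, averaged over stimulus locations."""
    return {
        c: compute_erp(epochs, condition=c, sensors=sensors, baseline=baseline)
        for c in conditions
    }


def additive_contrast(erp_a: np.ndarray, erp_v: np.ndarray, erp_av: np.ndarray) -> np.ndarray:
    """Pointwise additive contrast (ERP_A + ERP_V) - ERP_AV.

    Zero everywhere when the audiovisual response is exactly the sum of the
    unisensory responses; positive where the sum exceeds the audiovisual
    response (sub-additivity), negative under super-additivity.
    """
    erp_a, erp_v, erp_av = (np.asarray(e, dtype=float) for e in (erp_a, erp_v, erp_av))
    if not (erp_a.shape == erp_v.shape == erp_av.shape):
        raise ValueError("ERP timecourses must share one time axis")
    return erp_a + erp_v - erp_av
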