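"""Stereo rendering of spatially localised tones via interaural cues.

A virtual sound source sits on the display plane at horizontal offset ``x``
(metres, positive rightward) and forward distance ``z`` from the listener's
ears.  The two loudspeakers flank the display; the source azimuth is conveyed
through the interaural time difference (ITD) and interaural level difference
(ILD) implied by the left/right ear-to-source path lengths

    dL = sqrt((x + r)^2 + z^2),    dR = sqrt((x - r)^2 + z^2)

with head radius ``r`` added to ``x`` for the left channel and subtracted for
the right.  Arrival times are ``d / s`` (``s`` the speed of sound) and the
per-channel gains for a unit-amplitude source are ``1 / d`` (inverse-distance
attenuation).  Fractional delays are applied by resampling the waveform's time
axis with linear interpolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

__all__ = [
    "HeadGeometry",
    "StereoRender",
    "ToneSpec",
    "path_lengths",
    "itd_seconds",
    "ild_gains",
    "render_tone",
    "write_wav",
]

#: Approximate adult head radius in metres.
DEFAULT_HEAD_RADIUS_M = 0.08
#: Speed of sound in air at room temperature, m/s.
DEFAULT_SPEED_OF_SOUND_MPS = 343.0


class InvalidGeometryError(ValueError):
    """Head/source geometry violates its physical constraints."""


class DegenerateToneError(ValueError):
    """Requested tone is too short to contain at least two samples."""


@dataclass(frozen=True)
class HeadGeometry:
    """Source/listener geometry on the display plane.

    Parameters
    ----------
    x : float
        Horizontal offset of the virtual source from display centre, metres
        (signed; positive = right).
    z : float
        Forward distance from the ears to the display plane, metres.
    r : float
        Head radius, metres.
    s : float
        Speed of sound, metres/second.
    """

    x: float
    z: float
    r: float = DEFAULT_HEAD_RADIUS_M
    s: float = DEFAULT_SPEED_OF_SOUND_MPS

    def __post_init__(self) -> None:
        vals = (self.x, self.z, self.r, self.s)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidGeometryError(f"non-finite geometry: {vals}")
        if self.z <= 0:
            raise InvalidGeometryError(f"forward distance z must be > 0, got {self.z}")
        if self.r < 0:
            raise InvalidGeometryError(f"head radius r must be >= 0, got {self.r}")
        if self.s <= 0:
            raise InvalidGeometryError(f"speed of sound s must be > 0, got {self.s}")

    @classmethod
    def from_azimuth(
        cls,
        azimuth_deg: float,
        z: float,
        r: float = DEFAULT_HEAD_RADIUS_M,
        s: float = DEFAULT_SPEED_OF_SOUND_MPS,
    ) -> "HeadGeometry":
        """Build a geometry from a source azimuth in degrees of visual angle.

        The source lies on a plane at distance ``z``, so ``x = z * tan(azimuth)``.
        """
        if not math.isfinite(azimuth_deg):
            raise InvalidGeometryError(f"non-finite azimuth: {azimuth_deg}")
        return cls(x=z * math.tan(math.radians(azimuth_deg)), z=z, r=r, s=s)


@dataclass(frozen=True)
class ToneSpec:
    """Parameters of the source tone: a decaying sinusoid.

    The decay envelope is exponential, ``exp(-t / tau)``.
    """

    freq_hz: float = 850.0
    duration_s: float = 0.1
    sample_rate_hz: float = 44100.0
    decay_tau_s: float = 0.03


@dataclass(frozen=True)
class StereoRender:
    """A rendered stereo waveform plus the binaural cues that produced it."""

    left: np.ndarray
    right: np.ndarray
    sample_rate: float
    itd: float  # seconds, left minus right arrival time
    gains: tuple[float, float] = field(default=(1.0, 1.0))

    def __post_init__(self) -> None:
        if self.left.shape != self.right.shape:
            raise ValueError("left/right waveforms must have equal length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")


def path_lengths(geom: HeadGeometry) -> tuple[float, float]:
    """Ear-to-source path lengths ``(dL, dR)`` in metres."""
    dL = math.hypot(geom.x + geom.r, geom.z)
    dR = math.hypot(geom.x - geom.r, geom.z)
    return dL, dR


def itd_seconds(geom: HeadGeometry) -> tuple[float, float]:
    """Arrival times ``(tL, tR)`` of the source at each ear, seconds."""
    dL, dR = path_lengths(geom)
    return dL / geom.s, dR / geom.s


def ild_gains(geom: HeadGeometry) -> tuple[float, float]:
    """Per-channel amplitude gains ``(gL, gR) = (1/dL, 1/dR)`` for a unit source."""
    dL, dR = path_lengths(geom)
    return 1.0 / dL, 1.0 / dR


def max_ild(geom: HeadGeometry) -> float:
    """Absolute interaural level difference ``|gR - gL|`` in amplitude units."""
    gL, gR = ild_gains(geom)
    return abs(gR - gL)


def _delayed_tone(tone: ToneSpec, delay_s: float, n_samples: int) -> np.ndarray:
    """Decayed sinusoid delayed by ``delay_s`` via linear-interpolation resampling.

    Samples before onset are zero; the source signal is
    ``sin(2 pi f t) * exp(-t / tau)`` for ``0 <= t < duration``.
    """
    t_out = np.arange(n_samples) / tone.sample_rate_hz
    t_src = t_out - delay_s
    n_src = int(round(tone.duration_s * tone.sample_rate_hz))
    t_grid = np.arange(n_src) / tone.sample_rate_hz
    src = np.sin(2 * np.pi * tone.freq_hz * t_grid) * np.exp(-t_grid / tone.decay_tau_s)
    return np.interp(t_src, t_grid, src, left=0.0, right=0.0)


def render_tone(
    location_deg: float,
    z: float,
    tone: ToneSpec | None = None,
    r: float = DEFAULT_HEAD_RADIUS_M,
    s: float = DEFAULT_SPEED_OF_SOUND_MPS,
) -> StereoRender:
    """Render a decayed tone as a stereo pair carrying ITD and ILD cues.

    Parameters
    ----------
    location_deg : float
        Source azimuth in degrees of visual angle (``x = z tan(theta)``).
    z : float
        Viewing distance in metres.
    tone : ToneSpec, optional
        Source tone parameters; defaults to a 100 ms, 850 Hz tone at 44.1 kHz.

    Only the relative interaural delay ``max(tL,tR) - min(tL,tR)`` is applied
    (absolute propagation time carries no spatial information); the later ear
    is delayed, the earlier one starts at sample zero.
    """
    tone = tone or ToneSpec()
    if tone.duration_s * tone.sample_rate_hz < 2:
        raise DegenerateToneError(
            f"tone of {tone.duration_s}s at {tone.sample_rate_hz}Hz has < 2 samples"
        )
    geom = HeadGeometry.from_azimuth(location_deg, z=z, r=r, s=s)
    tL, tR = itd_seconds(geom)
    gL, gR = ild_gains(geom)
    base = min(tL, tR)
    n = int(round(tone.duration_s * tone.sample_rate_hz))
    left = gL * _delayed_tone(tone, tL - base, n)
    right = gR * _delayed_tone(tone, tR - base, n)
    return StereoRender(
        left=left, right=right, sample_rate=tone.sample_rate_hz, itd=tL - tR, gains=(gL, gR)
    )


def write_wav(render: StereoRender, path: str, pcm16: bool = False) -> None:
    """Write a stereo render as a WAV file (float32, or 16-bit PCM)."""
    stereo = np.stack([render.left, render.right], axis=1)
    if pcm16:
        peak = np.max(np.abs(stereo))
        scale = 32767.0 / peak if peak > 0 else 1.0
        wavfile.write(path, int(render.sample_rate), (stereo * scale).astype(np.int16))
    else:
        wavfile.write(path, int(render.sample_rate), stereo.astype(np.float32))
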