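"""Synthetic fixtures with exactly known ground truth.

These generators make every post-processing stage testable without a flow
solve: WSS vector series whose continuous-time TAWSS and OSI equal
prescribed targets, paired lumen pressure waveforms with prescribed
systolic amplification and peak lead, and seeded noise injection.

The OSI-targeted series uses a steady component plus an equal-dwell
reversing square wave because that family's (amplitude ratio -> OSI) map
is closed-form and exactly invertible: with square amplitude m = TAWSS
and steady part c = (1 - 2 OSI) m, the cycle integrals give back the
targets exactly — including on any even uniform sample grid, since the
periodic trapezoid rule integrates piecewise-constant signals exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple, Union

import numpy as np

from .indices import WSSSeries
from .waveforms import Waveform

__all__ = ["GroundTruth", "make_wss_series", "make_pressure_pair", "add_noise"]


@dataclass(frozen=True)
class GroundTruth:
    """Prescribed targets for the synthetic generators.

    ``target_tawss`` (Pa) and ``target_osi`` (in [0, 0.5)) drive
    :func:`make_wss_series`; ``amplification`` (percent) and ``peak_lead``
    (s) drive :func:`make_pressure_pair`.
    """

    target_tawss: float = 3.0
    target_osi: float = 0.25
    amplification: float = 25.0
    peak_lead: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_tawss <= 0:
            raise ValueError("target_tawss must be positive")
        if not 0.0 <= self.target_osi < 0.5:
            raise ValueError(
                f"target_osi must be in [0, 0.5), got {self.target_osi}"
            )


def make_wss_series(truth: GroundTruth, n_points: int = 16,
                    n_steps: int = 200,
                    period: float = 1.0) -> Tuple[WSSSeries, GroundTruth]:
    """WSS series whose exact TAWSS and OSI equal the prescribed targets.

    Each wall point carries the same target pair in a seeded random wall
    direction with a seeded integer phase offset of the reversal (neither
    changes the cycle integrals).  ``n_steps`` should be even for the
    square-wave dwell times to be exactly equal on the sample grid.
    """
    if n_steps < 16:
        raise ValueError("n_steps must be >= 16")
    rng = np.random.default_rng(truth.seed)
    angles = rng.uniform(0.0, 2.0 * np.pi, size=n_points)
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=-1)

    m = truth.target_tawss
    c = (1.0 - 2.0 * truth.target_osi) * m
    if truth.target_osi == 0.0:
        signal = np.full((n_points, n_steps), m)
    else:
        square = np.where(np.arange(n_steps) < n_steps // 2, 1.0, -1.0)
        phases = rng.integers(0, n_steps, size=n_points)
        signal = np.stack([c + m * np.roll(square, ph) for ph in phases])
    vectors = signal[:, :, None] * dirs[:, None, :]
    arc = np.linspace(0.0, 1.0, n_points) * 0.1
    series = WSSSeries(arc_length=arc, vectors=vectors, period=period)
    return series, truth


def make_pressure_pair(truth: GroundTruth,
                       base: Waveform) -> Tuple[Waveform, Waveform]:
    """(test, reference) waveform pair with exact systolic targets.

    The reference is ``base``; the test waveform is the base scaled about
    its diastolic floor so its systolic peak exceeds the reference peak by
    exactly ``truth.amplification`` percent, then advanced in time by
    ``truth.peak_lead`` (positive = test peaks earlier).  Integer-sample
    leads use an exact circular shift; other leads use the spectral shift,
    which is exact for the band-limited synthesized pulses.
    """
    if abs(truth.peak_lead) >= base.period:
        raise ValueError("peak lead must be smaller than the period")
    peak = float(np.max(base.values))
    floor = float(np.min(base.values))
    if peak <= 0:
        raise ValueError("base waveform must have a positive maximum")
    if peak == floor:
        raise ValueError("base waveform is constant")
    factor = 1.0 + (truth.amplification / 100.0) * peak / (peak - floor)

    n = base.n_samples
    dt = base.period / n
    shift = truth.peak_lead / dt
    if np.isclose(shift, round(shift), atol=1e-12):
        shifted = np.roll(base.values, -int(round(shift)))
    else:
        spec = np.fft.rfft(base.values)
        k = np.arange(spec.size)
        spec *= np.exp(2j * np.pi * k * shift / n)
        shifted = np.fft.irfft(spec, n)
    test = Waveform(values=floor + factor * (shifted - floor),
                    period=base.period, unit=base.unit)
    return test, base


def add_noise(obj: Union[Waveform, WSSSeries], relative_sd: float,
              seed: int) -> Union[Waveform, WSSSeries]:
    """Add zero-mean Gaussian noise scaled by the signal RMS.

    Deterministic per seed; ``relative_sd = 0`` returns an identical copy.
    """
    if relative_sd < 0:
        raise ValueError("relative_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if isinstance(obj, Waveform):
        rms = float(np.sqrt(np.mean(obj.values**2)))
        noise = rng.normal(0.0, relative_sd * rms, size=obj.values.shape)
        return replace(obj, values=obj.values + noise)
    if isinstance(obj, WSSSeries):
        rms = float(np.sqrt(np.mean(obj.vectors**2)))
        noise = rng.normal(0.0, relative_sd * rms, size=obj.vectors.shape)
        return replace(obj, vectors=obj.vectors + noise)
    raise TypeError(f"unsupported type {type(obj).__name__}")
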