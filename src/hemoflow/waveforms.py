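"""Physiological pulse waveforms and analytic flow oracles.

The inlet-velocity and outlet-pressure waveform shapes used clinically are
not available in closed form, so pulses are synthesized from a smooth
periodic bump (a von Mises kernel truncated to a configurable number of
Fourier harmonics) constrained to hit the systolic level exactly at the
systolic peak time and the diastolic level as its minimum.

Also here: Fourier tooling, the classical Womersley pulsatile-tube
solution and the Poiseuille wall-shear formula (the analytic oracles used
to verify the flow solver), waveform unit conversions, and the
waveform-comparison metrics (relative-L2 percent difference, systolic
amplification and peak lead time).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from scipy.special import ive, jv

from . import presets
from .rheology import RheologyParams

__all__ = [
    "WaveformSpec",
    "Waveform",
    "synthesize_pulse",
    "fourier_decompose",
    "fourier_reconstruct",
    "womersley_velocity",
    "poiseuille_wss",
    "flow_rate_from_velocity",
    "waveform_percent_difference",
    "systolic_metrics",
    "waveform_to_csv",
    "waveform_from_csv",
]

VALID_UNITS = ("mmHg", "m/s", "mL/s", "Pa")


@dataclass(frozen=True)
class WaveformSpec:
    """Parameters of a periodic physiological pulse.

    ``systolic_level``/``diastolic_level`` are in mmHg for pressure or m/s
    for velocity, selected by ``unit``.  ``sharpness`` controls the width
    of the systolic bump (larger = narrower systole).
    """

    period: float = presets.CARDIAC_PERIOD
    peak_time: float = presets.SYSTOLIC_PEAK_TIME
    systolic_level: float = presets.SYSTOLIC_PRESSURE_MMHG
    diastolic_level: float = presets.DIASTOLIC_PRESSURE_MMHG
    harmonic_count: int = 8
    unit: str = "mmHg"
    sharpness: float = 8.0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if not 0 < self.peak_time < self.period:
            raise ValueError(
                f"peak_time must lie in (0, period), got {self.peak_time}"
            )
        if self.systolic_level <= self.diastolic_level:
            raise ValueError("systolic_level must exceed diastolic_level")
        if self.harmonic_count < 1:
            raise ValueError("harmonic_count must be >= 1")
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}")
        if self.sharpness <= 0:
            raise ValueError("sharpness must be positive")


@dataclass(frozen=True)
class Waveform:
    """One period of a uniformly sampled periodic signal.

    Samples live on the open grid t_k = k*period/n, k = 0..n-1; the value
    at t = period wraps around to ``values[0]``.
    """

    values: np.ndarray
    period: float
    unit: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("values must be a 1-D array with >= 2 samples")
        if not np.all(np.isfinite(v)):
            raise ValueError("waveform samples must be finite")
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}")
        if self.period <= 0:
            raise ValueError("period must be positive")
        object.__setattr__(self, "values", v)

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * (self.period / self.n_samples)

    def sample_at(self, t) -> np.ndarray:
        """Periodic linear interpolation at arbitrary times."""
        t = np.mod(np.asarray(t, dtype=float), self.period)
        tg = np.append(self.times, self.period)
        vg = np.append(self.values, self.values[0])
        return np.interp(t, tg, vg)

    def resampled(self, n: int) -> "Waveform":
        return replace(self, values=self.sample_at(np.arange(n) * self.period / n))

    def mean(self) -> float:
        """Time mean over the period (exact for the periodic trapezoid rule)."""
        return float(np.mean(self.values))


def _vonmises_coefficients(kappa: float, n_harmonics: int,
                           rng: Optional[np.random.Generator]) -> np.ndarray:
    """Cosine-series coefficients a_k > 0 of exp(kappa*(cos th - 1)).

    a_0 = I_0(kappa)e^-kappa, a_k = 2 I_k(kappa)e^-kappa (exponentially
    scaled Bessel ive avoids overflow).  Optional seeded jitter perturbs the
    harmonic amplitudes while keeping them positive, so the global maximum
    stays exactly at th = 0.
    """
    k = np.arange(n_harmonics + 1)
    a = ive(k, kappa)
    a[1:] *= 2.0
    if rng is not None:
        a[1:] *= 1.0 + 0.05 * rng.uniform(-1.0, 1.0, size=n_harmonics)
    return a


def synthesize_pulse(spec: WaveformSpec, seed: Optional[int] = None,
                     n_samples: int = 200) -> Waveform:
    """Generate a smooth periodic pulse honouring the spec's constraints.

    The pulse attains ``systolic_level`` exactly at ``peak_time`` (all
    cosine coefficients about the peak are positive, so the truncated
    series peaks there) and ``diastolic_level`` as its minimum over the
    period.  Deterministic for a fixed (spec, seed) pair; ``seed=None``
    yields the canonical unjittered shape.
    """
    rng = np.random.default_rng(seed) if seed is not None else None
    a = _vonmises_coefficients(spec.sharpness, spec.harmonic_count, rng)

    def g(theta):
        return a[0] + sum(a[k] * np.cos(k * np.asarray(theta))
                          for k in range(1, a.size))

    g_max = float(g(0.0))
    t = np.arange(n_samples) * (spec.period / n_samples)
    theta = 2.0 * np.pi * (t - spec.peak_time) / spec.period
    gv = g(theta)
    # normalize against the sampled minimum so the diastolic level is
    # attained exactly on the grid; the analytic maximum at peak_time maps
    # exactly to the systolic level (all cosine coefficients positive)
    g_min = float(np.min(gv))
    scale = (spec.systolic_level - spec.diastolic_level) / (g_max - g_min)
    values = spec.diastolic_level + scale * (gv - g_min)
    return Waveform(values=values, period=spec.period, unit=spec.unit)


def fourier_decompose(w: Waveform, n_harmonics: int) -> np.ndarray:
    """Complex harmonic coefficients c_0..c_K of a sampled waveform.

    c_0 is the (real) time mean; the signal is reconstructed as
    c_0 + sum_k 2*Re(c_k exp(2*pi*i*k*t/T)).
    """
    n = w.n_samples
    if n_harmonics < 0 or n_harmonics > n // 2:
        raise ValueError(
            f"n_harmonics must be in [0, {n // 2}] for {n} samples"
        )
    c = np.fft.rfft(w.values) / n
    return c[: n_harmonics + 1]


def fourier_reconstruct(coeffs: np.ndarray, n_samples: int,
                        period: float, unit: str = "Pa") -> Waveform:
    """Inverse of :func:`fourier_decompose` on a fresh uniform grid."""
    t = np.arange(n_samples) * (period / n_samples)
    vals = np.full(n_samples, np.real(coeffs[0]))
    for k in range(1, len(coeffs)):
        vals += 2.0 * np.real(coeffs[k] * np.exp(2j * np.pi * k * t / period))
    return Waveform(values=vals, period=period, unit=unit)


def womersley_velocity(radius: float, pressure_gradient_harmonics,
                       rheology: RheologyParams, r, t,
                       period: float = presets.CARDIAC_PERIOD):
    """Axial velocity of pulsatile laminar flow in a rigid circular tube.

    ``pressure_gradient_harmonics`` is a complex array G_0..G_K encoding
    the axial pressure gradient dp/dz(t) = Re(sum_k G_k exp(i k w t)) in
    Pa/m with w = 2*pi/period.  The k = 0 term gives the Poiseuille
    paraboloid; each oscillatory harmonic contributes the classical
    Bessel-function profile.  Newtonian rheology only.  ``r`` and ``t``
    broadcast; returns velocity in m/s with no-slip at ``r = radius``.
    """
    if not rheology.is_newtonian:
        raise ValueError("Womersley oracle requires Newtonian rheology "
                         "(mu_zero == mu_inf)")
    if radius <= 0:
        raise ValueError("radius must be positive")
    r = np.asarray(r, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(np.abs(r) > radius * (1 + 1e-12)):
        raise ValueError("|r| must be <= radius")
    mu = rheology.mu_inf
    rho = rheology.density
    nu = mu / rho
    omega = 2.0 * np.pi / period
    G = np.asarray(pressure_gradient_harmonics, dtype=complex)

    u = -np.real(G[0]) * (radius**2 - r**2) / (4.0 * mu)
    u = np.broadcast_to(u, np.broadcast_shapes(r.shape, t.shape)).copy()
    for k in range(1, len(G)):
        if G[k] == 0:
            continue
        beta = np.sqrt(-1j * k * omega / nu)
        prof = 1.0 - jv(0, beta * r) / jv(0, beta * radius)
        u += np.real((1j * G[k] / (rho * k * omega)) * prof
                     * np.exp(1j * k * omega * t))
    return u


def womersley_wall_shear(radius: float, pressure_gradient_harmonics,
                         rheology: RheologyParams, t,
                         period: float = presets.CARDIAC_PERIOD):
    """Analytic wall shear stress tau_w(t) = -mu du/dr |_(r=R), Pa.

    Companion oracle to :func:`womersley_velocity`; positive when the flow
    drags the wall in the +z direction.
    """
    if not rheology.is_newtonian:
        raise ValueError("Womersley oracle requires Newtonian rheology")
    mu = rheology.mu_inf
    rho = rheology.density
    nu = mu / rho
    omega = 2.0 * np.pi / period
    G = np.asarray(pressure_gradient_harmonics, dtype=complex)
    t = np.asarray(t, dtype=float)

    tau = np.full(t.shape, -np.real(G[0]) * radius / 2.0)
    for k in range(1, len(G)):
        if G[k] == 0:
            continue
        beta = np.sqrt(-1j * k * omega / nu)
        # d/dr [1 - J0(beta r)/J0(beta R)] = beta J1(beta r)/J0(beta R)
        dprof = beta * jv(1, beta * radius) / jv(0, beta * radius)
        tau += np.real(-mu * (1j * G[k] / (rho * k * omega)) * dprof
                       * np.exp(1j * k * omega * t))
    return tau


def poiseuille_wss(flow_rate: float, radius: float, viscosity: float) -> float:
    """Wall shear stress of steady Poiseuille tube flow: 4*mu*Q/(pi*R^3), Pa."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return 4.0 * viscosity * flow_rate / (np.pi * radius**3)


def flow_rate_from_velocity(w: Waveform, diameter_mm: float) -> Waveform:
    """Convert a mean-velocity waveform (m/s) to flow rate in mL/s.

    Q(t) = u(t) * pi * (d/2)^2 with d the vessel diameter.
    """
    if w.unit != "m/s":
        raise ValueError(f"expected velocity waveform in m/s, got {w.unit!r}")
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    area_m2 = np.pi * (diameter_mm * 1e-3 / 2.0) ** 2
    return Waveform(values=w.values * area_m2 * 1e6, period=w.period,
                    unit="mL/s")


def _common_grid(a: Waveform, b: Waveform) -> Tuple[np.ndarray, np.ndarray]:
    n = max(a.n_samples, b.n_samples)
    t = np.arange(n) * (a.period / n)
    return a.sample_at(t), b.sample_at(t)


def waveform_percent_difference(a: Waveform, b: Waveform,
                                symmetric: bool = False) -> float:
    """Percent difference 100*||a - b||_2 / ||b||_2 with b the reference.

    Waveforms are resampled to a common uniform grid first.  The symmetric
    variant normalizes by the mean of the two norms instead.
    """
    if a.unit != b.unit:
        raise ValueError(f"unit mismatch: {a.unit!r} vs {b.unit!r}")
    if not np.isclose(a.period, b.period):
        raise ValueError("waveform periods differ")
    av, bv = _common_grid(a, b)
    diff = np.linalg.norm(av - bv)
    ref = (0.5 * (np.linalg.norm(av) + np.linalg.norm(bv)) if symmetric
           else np.linalg.norm(bv))
    if ref == 0:
        raise ValueError("reference waveform has zero norm")
    return float(100.0 * diff / ref)


def _refined_peak(w: Waveform) -> Tuple[float, float]:
    """(peak time, peak value) with parabolic sub-sample refinement."""
    v = w.values
    n = v.size
    j = int(np.argmax(v))
    ym, y0, yp = v[(j - 1) % n], v[j], v[(j + 1) % n]
    denom = ym - 2.0 * y0 + yp
    dt = w.period / n
    if denom < 0:  # proper parabolic cap
        off = 0.5 * (ym - yp) / denom
        return (j + off) * dt, y0 - 0.25 * (ym - yp) * off
    return j * dt, y0


def systolic_metrics(test: Waveform, reference: Waveform) -> dict:
    """Systolic amplification (percent) and peak lead time (s).

    amplification = 100*(max(test) - max(reference))/max(reference);
    peak_lead = t_peak(reference) - t_peak(test), positive when the test
    waveform peaks earlier.  Peaks are located with parabolic sub-sample
    refinement; the lead is wrapped into (-T/2, T/2].
    """
    if test.unit != reference.unit:
        raise ValueError(f"unit mismatch: {test.unit!r} vs {reference.unit!r}")
    if not np.isclose(test.period, reference.period):
        raise ValueError("waveform periods differ")
    t_test, v_test = _refined_peak(test)
    t_ref, v_ref = _refined_peak(reference)
    if v_ref <= 0:
        raise ValueError("reference maximum must be positive")
    lead = t_ref - t_test
    half = reference.period / 2.0
    lead = (lead + half) % reference.period - half
    return {
        "amplification": float(100.0 * (v_test - v_ref) / v_ref),
        "peak_lead": float(lead),
    }


def waveform_to_csv(w: Waveform, path) -> None:
    """Write ``time_s,value`` rows; the header comment carries the unit tag."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# unit: {w.unit}\n")
        fh.write(f"# period_s: {float(w.period)!r}\n")
        fh.write("time_s,value\n")
        for t, v in zip(w.times, w.values):
            fh.write(f"{float(t)!r},{float(v)!r}\n")


def waveform_from_csv(path) -> Waveform:
    """Read a waveform CSV written by :func:`waveform_to_csv`.

    Also accepts plain two-column CSVs without metadata comments, in which
    case the period is inferred from the time column (assumed to span one
    period on a uniform open grid) and the unit defaults are rejected —
    a ``# unit:`` line is required.
    """
    path = Path(path)
    unit = None
    period = None
    times, vals = [], []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("unit:"):
                    unit = body.split(":", 1)[1].strip()
                elif body.startswith("period_s:"):
                    period = float(body.split(":", 1)[1])
                continue
            if line.lower().startswith("time_s"):
                continue
            t_str, v_str = line.split(",")
            times.append(float(t_str))
            vals.append(float(v_str))
    if unit is None:
        raise ValueError(f"{path}: missing '# unit:' header line")
    if len(vals) < 2:
        raise ValueError(f"{path}: too few samples")
    times = np.asarray(times)
    if period is None:
        period = float(times[-1] + (times[-1] - times[-2]))
    return Waveform(values=np.asarray(vals), period=period, unit=unit)
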