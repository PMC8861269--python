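"""Simulated electrophysiology derived from belief and precision traces.

One movement (time step) is taken to last 250 ms; with 16 belief-update
iterations per step the iteration interval is dt = 15.625 ms (64 Hz sampling),
so one belief-update cycle per movement is a 4 Hz (theta) rhythm.

- *Firing rates* are the Bayesian-model-average state expectations: one unit
  per (represented time point, location) pair — ``n_states · (n_moves + 1)``
  units, 1,100 for a 10-move trial on the 10×10 grid.
- *Local field potentials* are the rate of change of the firing rates.
- *Dopamine* is the precision γ over policies (tonic), and the positive part
  of its rate of change (phasic).  Precision is updated when new observations
  arrive, i.e. at time-step boundaries, so phasic events sit at iteration
  indices that are multiples of ``iterations_per_step``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal

from .environment import SimulationRecord

#: Default step duration (seconds per movement).
STEP_DURATION_S = 0.25


@dataclass
class EphysTraces:
    """Bundle of simulated electrophysiological signals."""

    time_s: np.ndarray
    rates: np.ndarray  # (n_iterations, n_units)
    lfp: np.ndarray  # (n_iterations, n_units) first differences / dt
    lfp_avg: np.ndarray  # (n_iterations,) signed mean across units
    lfp_mua: np.ndarray  # (n_iterations,) mean rectified LFP (activity envelope)
    da_tonic: np.ndarray
    da_phasic: np.ndarray
    dt: float
    unit_labels: list[tuple[int, int]]  # (tau, state) per unit

    @property
    def n_units(self) -> int:
        return self.rates.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format export (time_s, unit_or_channel, signal_type, value)."""
        frames = []
        for name, tr in (
            ("lfp_avg", self.lfp_avg),
            ("lfp_mua", self.lfp_mua),
            ("lfp_theta", bandpass_theta(self.lfp_mua, self.dt)),
            ("da_tonic", self.da_tonic),
            ("da_phasic", self.da_phasic),
        ):
            frames.append(
                pd.DataFrame(
                    {"time_s": self.time_s, "unit_or_channel": -1,
                     "signal_type": name, "value": tr}
                )
            )
        for j in range(self.n_units):
            frames.append(
                pd.DataFrame(
                    {"time_s": self.time_s, "unit_or_channel": j,
                     "signal_type": "rate", "value": self.rates[:, j]}
                )
            )
        return pd.concat(frames, ignore_index=True)


def firing_rate_raster(record: SimulationRecord) -> np.ndarray:
    """Unit × iteration table of simulated firing rates.

    Unit ``(τ, j)`` at iteration ``k`` holds the Bayesian-model-average
    probability of location ``j`` at represented time point ``τ``; at every
    iteration the units belonging to one τ sum to 1 (so the full raster sums
    to ``n_moves + 1`` across units).  Returned shape is
    ``(n_iterations, n_units)`` with units ordered (τ=0 states…, τ=1 states…).
    """
    if record.raster is None:
        raise ValueError("record carries no belief raster")
    n_iter, n_times, n_states = record.raster.shape
    # guard against float rounding of the model-average mixture
    return np.clip(record.raster.reshape(n_iter, n_times * n_states), 0.0, 1.0)


def local_field_potentials(
    raster: np.ndarray, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-unit LFP (first difference of firing rate / dt) and their average.

    A constant raster yields identically zero LFPs.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    raster = np.asarray(raster, dtype=float)
    lfp = np.zeros_like(raster)
    lfp[1:] = np.diff(raster, axis=0) / dt
    return lfp, lfp.mean(axis=1)


def population_activity(lfp: np.ndarray) -> np.ndarray:
    """Mean rectified LFP across units (the multi-unit activity envelope).

    Because the units representing one time point always carry a normalised
    belief, the *signed* unit-mean LFP cancels identically; the induced
    population response lives in the envelope of the per-unit rates of
    change, which beats at one belief-update cycle per movement (theta under
    the 250 ms/step convention).
    """
    return np.abs(np.asarray(lfp, dtype=float)).mean(axis=1)


def dopamine_trace(
    gamma_per_step: np.ndarray,
    iterations_per_step: int,
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Tonic and phasic dopamine traces from the per-step precision.

    Precision is revised only when a new observation arrives, so the tonic
    trace holds each step's converged γ constant over the step's iterations;
    the phasic trace is the positive part of its first difference divided by
    dt, hence nonzero only at iteration indices that are multiples of
    ``iterations_per_step``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    gamma = np.asarray(gamma_per_step, dtype=float)
    tonic = np.repeat(gamma, iterations_per_step)
    phasic = np.zeros_like(tonic)
    phasic[1:] = np.maximum(np.diff(tonic), 0.0) / dt
    return tonic, phasic


def compute_ephys(
    record: SimulationRecord,
    step_duration_s: Optional[float] = None,
) -> EphysTraces:
    """Assemble all simulated signals for one trial record."""
    step_s = record.step_duration_s if step_duration_s is None else step_duration_s
    dt = step_s / record.iterations_per_step
    rates = firing_rate_raster(record)
    lfp, lfp_avg = local_field_potentials(rates, dt)
    lfp_mua = population_activity(lfp)
    tonic, phasic = dopamine_trace(
        np.asarray(record.gamma_per_step), record.iterations_per_step, dt
    )
    n_iter = rates.shape[0]
    n_times = record.n_moves + 1
    labels = [(tau, j) for tau in range(n_times) for j in range(record.n_states)]
    return EphysTraces(
        time_s=np.arange(n_iter) * dt,
        rates=rates,
        lfp=lfp,
        lfp_avg=lfp_avg,
        lfp_mua=lfp_mua,
        da_tonic=tonic[:n_iter],
        da_phasic=phasic[:n_iter],
        dt=dt,
        unit_labels=labels,
    )


def bandpass_theta(
    trace: np.ndarray,
    dt: float,
    center_hz: float = 4.0,
    half_width_hz: float = 2.0,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase band-pass around the theta frequency (default 2–6 Hz).

    A second-order Butterworth filter applied forward–backward; a sinusoid at
    the centre frequency passes with < 10 % attenuation and a constant input
    maps to ≈ 0.
    """
    fs = 1.0 / dt
    lo, hi = center_hz - half_width_hz, center_hz + half_width_hz
    if hi >= fs / 2 or lo <= 0:
        raise ValueError("band outside (0, Nyquist)")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(trace, dtype=float))


def time_frequency(
    average_lfp: np.ndarray,
    dt: float,
    window_s: float = 1.0,
    overlap: float = 0.75,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time spectral power of the average LFP.

    Returns (frequencies, times, power); power is nonnegative.  Under the
    250 ms/step convention the time-averaged spectrum of a navigation run
    peaks in the theta band (3–5 Hz).
    """
    x = np.asarray(average_lfp, dtype=float)
    fs = 1.0 / dt
    nperseg = int(round(window_s * fs))
    if len(x) < nperseg:
        raise ValueError("trace shorter than one analysis window")
    f, t, S = signal.spectrogram(
        x, fs=fs, nperseg=nperseg, noverlap=int(nperseg * overlap),
        detrend="constant", scaling="density", mode="psd",
    )
    return f, t, S


def spectral_peak_hz(
    average_lfp: np.ndarray,
    dt: float,
    fmin: float = 1.0,
    fmax: Optional[float] = None,
    **kwargs,
) -> float:
    """Frequency of the maximum of the time-averaged spectrum (excluding
    near-DC bins below ``fmin``)."""
    f, _, S = time_frequency(average_lfp, dt, **kwargs)
    mean_spec = S.mean(axis=1)
    mask = f >= fmin
    if fmax is not None:
        mask &= f <= fmax
    return float(f[mask][np.argmax(mean_spec[mask])])
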