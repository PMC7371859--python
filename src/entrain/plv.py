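"""Phase-locking value (PLV) between EEG and an offset-aligned reference.

PLV = (1/N) | sum_n exp(i (phi_ong(n) - phi_ref(n))) | over trials n; values
range 0..1.  The reference wave oscillates at the individual alpha
frequency with phase 0 at the burst offset.  Phase extraction uses complex
Morlet wavelets with 5 cycles and a Gaussian envelope truncated at +/-3
standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import oaconvolve

from . import montage
from .preprocess import TrialSet

MORLET_CYCLES = 5.0
GAUSS_SD_TRUNC = 3.0
ANALYSIS_WINDOW = (-3.5, 2.5)       # s relative to burst offset
DEFAULT_BASELINE = (-3.0, -2.5)     # s relative to burst offset
DEFAULT_FREQ_GRID = np.arange(5.0, 30.0 + 1e-9, 0.5)


@dataclass(frozen=True)
class ReferenceWave:
    """Constant-frequency phase series aligned to the burst offset."""

    iaf: float
    times: np.ndarray
    phase: np.ndarray  # wrapped to (-pi, pi]


def _wrap(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into (-pi, pi]."""
    return -((-np.asarray(phi) + np.pi) % (2 * np.pi) - np.pi)


def reference_wave(iaf: float, times: np.ndarray, offset_time: float = 0.0
                   ) -> ReferenceWave:
    """Phase = wrap(2*pi*iaf*(t - offset)); phase 0 at the burst offset."""
    if iaf <= 0:
        raise ValueError("iaf must be positive")
    times = np.asarray(times, dtype=float)
    phase = _wrap(2 * np.pi * iaf * (times - offset_time))
    return ReferenceWave(iaf, times, np.asarray(phase))


@dataclass
class PhaseTensor:
    """Instantaneous phase per trial x channel x frequency x time."""

    phase: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    fs: float
    edge_valid: np.ndarray  # (n_freqs, n_times): full wavelet support
    channel_names: list[str]
    conditions: list[str]


def _morlet_kernel(freq: float, fs: float) -> np.ndarray:
    sigma_t = MORLET_CYCLES / (2 * np.pi * freq)
    half = int(np.ceil(GAUSS_SD_TRUNC * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    return np.exp(-(t ** 2) / (2 * sigma_t ** 2)) * np.exp(2j * np.pi * freq * t)


def wavelet_phase(ts: TrialSet, freqs: np.ndarray | None = None,
                  channels: list[str] | None = None, decim: int = 1,
                  window: tuple[float, float] = ANALYSIS_WINDOW) -> PhaseTensor:
    """Complex Morlet phase decomposition of the analysis window."""
    if freqs is None:
        freqs = DEFAULT_FREQ_GRID
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(freqs >= ts.fs / 2):
        raise ValueError("frequency at or above Nyquist")
    if channels is None:
        channels = list(ts.channel_names)
    cidx = ts.channel_index(channels)

    sel = (ts.times >= window[0] - 1e-9) & (ts.times <= window[1] + 1e-9)
    data = ts.data[:, cidx, :]
    out_idx = np.flatnonzero(sel)[::decim]
    times = ts.times[out_idx]
    n_tr, n_ch = data.shape[0], len(cidx)

    phase = np.empty((n_tr, n_ch, len(freqs), len(out_idx)))
    edge_valid = np.ones((len(freqs), len(out_idx)), dtype=bool)
    for fi, f in enumerate(freqs):
        kern = _morlet_kernel(f, ts.fs)
        half = (len(kern) - 1) // 2
        conv = oaconvolve(data, kern[None, None, :], mode="same", axes=2)
        phase[:, :, fi, :] = np.angle(conv[:, :, out_idx])
        edge_valid[fi] = (out_idx >= half) & (out_idx < ts.n_samples - half)
    phase = _wrap(phase)
    return PhaseTensor(phase, freqs, times, ts.fs / decim, edge_valid,
                       list(channels), list(ts.conditions))


@dataclass
class PLVMap:
    """PLV over channels x frequencies x time (or pulse index)."""

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray          # seconds, or pulse index for pulse-locked maps
    channel_names: list[str]
    n: int                     # trial count
    normalization: str = "raw"  # 'raw' | 'baseline_relative'

    def posterior_mean(self) -> np.ndarray:
        """Channel-average over the posterior set: (n_freqs, n_times)."""
        posterior = montage.posterior_channels(self.channel_names)
        idx = ([self.channel_names.index(c) for c in posterior]
               if posterior else list(range(len(self.channel_names))))
        return self.values[idx].mean(axis=0)


def plv(ph: PhaseTensor, ref: ReferenceWave) -> PLVMap:
    """Modulus of the across-trial mean unit phasor of phase differences."""
    if ph.phase.shape[0] < 2:
        raise ValueError("PLV needs at least 2 trials")
    ref_phase = np.interp(ph.times, ref.times, np.unwrap(ref.phase))
    diff = ph.phase - ref_phase[None, None, None, :]
    values = np.abs(np.exp(1j * diff).mean(axis=0))
    return PLVMap(values, ph.freqs.copy(), ph.times.copy(),
                  list(ph.channel_names), ph.phase.shape[0], "raw")


def plv_from_phases(phase_diffs: np.ndarray, axis: int = 0) -> np.ndarray:
    """Direct PLV of explicit phase differences along the trial axis."""
    return np.abs(np.exp(1j * np.asarray(phase_diffs)).mean(axis=axis))


def baseline_normalize(pm: PLVMap, baseline: tuple[float, float] = DEFAULT_BASELINE
                       ) -> PLVMap:
    """Relative normalization: divide by the scalar baseline-window mean."""
    if pm.normalization != "raw":
        raise ValueError("already normalized")
    sel = (pm.times >= baseline[0] - 1e-9) & (pm.times <= baseline[1] + 1e-9)
    if not sel.any():
        raise ValueError("baseline window outside the analysis window")
    base = pm.values[:, :, sel].mean(axis=2, keepdims=True)
    if np.any(base == 0):
        raise ValueError("baseline mean is zero")
    return replace(pm, values=pm.values / base, normalization="baseline_relative")


def pulse_locked_plv(ts: TrialSet, iaf: float,
                     channels: list[str] | None = None) -> PLVMap:
    """PLV at the IAF evaluated at each of the aligned pulse times.

    Only valid for rhythmic trials (constant inter-pulse intervals).  The
    output has n_pulses + 2 entries: 'pre' (one IAF cycle before the first
    pulse), the pulses, and 'post' (one cycle after the last pulse).
    """
    bad = [c for c in ts.conditions if c not in ("rhythmic", "sham")]
    if bad:
        raise ValueError("pulse-locked PLV requires rhythmic (or sham-rhythmic) trials")
    pulses = ts.pulse_times[0]
    for p in ts.pulse_times[1:]:
        if len(p) != len(pulses) or np.max(np.abs(p - pulses)) > 1.0 / (4 * iaf):
            raise ValueError("pulse times are not aligned across trials")
    eval_times = np.concatenate([[pulses[0] - 1.0 / iaf], pulses,
                                 [pulses[-1] + 1.0 / iaf]])
    ph = wavelet_phase(ts, freqs=np.array([iaf]), channels=channels,
                       window=(float(eval_times[0]) - 0.2, float(eval_times[-1]) + 0.2))
    ref = reference_wave(iaf, ph.times, offset_time=0.0)
    diff = ph.phase[:, :, 0, :] - ref.phase[None, None, :]
    idx = [int(np.argmin(np.abs(ph.times - t))) for t in eval_times]
    values = np.abs(np.exp(1j * diff[:, :, idx]).mean(axis=0))[:, None, :]
    return PLVMap(values, np.array([iaf]), np.arange(len(eval_times), dtype=float) - 1,
                  list(ph.channel_names), ts.n_trials, "raw")
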