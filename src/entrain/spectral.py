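"""Individual alpha frequency (IAF) estimation from resting-state EEG.

Pipeline: 2 s epochs with 50% overlap -> common-average re-reference ->
detrend/demean -> Butterworth band-pass 0.1-40 Hz -> variance-based epoch
rejection -> multitaper (DPSS) spectrum on a 1-20 Hz grid with 0.5 Hz
steps -> peak search in 8-12 Hz over posterior channels.  If the eyes-open
recording yields no acceptable peak, the eyes-closed recording is used;
failing both, the result carries ``iaf=None``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, detrend, sosfiltfilt
from scipy.signal.windows import dpss

from . import montage
from .core_io import Recording

FREQ_GRID = np.arange(1.0, 20.0 + 1e-9, 0.5)
ALPHA_BAND = (8.0, 12.0)
EPOCH_SECONDS = 2.0
PEAK_PROMINENCE_FACTOR = 1.5


@dataclass
class SpectrumResult:
    """Trial-averaged multitaper spectrum with the picked alpha peak."""

    frequencies: np.ndarray          # Hz, the 1-20 Hz grid
    power: np.ndarray                # (n_channels, n_freqs) trial average
    posterior_power: np.ndarray      # (n_freqs,) posterior-channel average
    iaf: float | None
    source_condition: str | None     # 'eyes_open' | 'eyes_closed' | None
    channel_names: list[str]


def _epochs(rec: Recording) -> np.ndarray:
    """2 s epochs, 50% overlap: (n_epochs, n_channels, n_samples)."""
    n = int(round(EPOCH_SECONDS * rec.fs))
    step = n // 2
    starts = range(0, rec.n_samples - n + 1, step)
    return np.stack([rec.data[:, s:s + n] for s in starts])


def _preprocess_epochs(ep: np.ndarray, fs: float) -> np.ndarray:
    ep = ep - ep.mean(axis=1, keepdims=True)          # common average
    ep = detrend(ep, axis=2, type="linear")
    ep = ep - ep.mean(axis=2, keepdims=True)
    sos = butter(4, [0.1, 40.0], btype="bandpass", fs=fs, output="sos")
    ep = sosfiltfilt(sos, ep, axis=2)
    # variance-based epoch rejection (automated stand-in for inspection)
    v = ep.var(axis=(1, 2))
    q1, q3 = np.percentile(v, [25, 75])
    keep = v <= q3 + 1.5 * (q3 - q1)
    return ep[keep]


def _multitaper_power(ep: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """DPSS multitaper PSD per channel, averaged over epochs and tapers."""
    n = ep.shape[2]
    tapers = dpss(n, NW=2, Kmax=3)
    # (tapers, epochs, channels, samples) -> rFFT power
    tapered = ep[None, :, :, :] * tapers[:, None, None, :]
    spec = np.fft.rfft(tapered, axis=3)
    psd = (np.abs(spec) ** 2).mean(axis=(0, 1))        # (channels, n_freqs_full)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return freqs, psd


def _power_on_grid(freqs: np.ndarray, psd: np.ndarray) -> np.ndarray:
    out = np.empty((psd.shape[0], len(FREQ_GRID)))
    for i, f in enumerate(FREQ_GRID):
        out[:, i] = psd[:, np.argmin(np.abs(freqs - f))]
    return out


def _pick_peak(posterior: np.ndarray) -> float | None:
    """Local max in 8-12 Hz exceeding the fitted 1/f trend by the factor."""
    grid = FREQ_GRID
    trend_mask = (grid >= 1.0) & ~((grid >= 7.0) & (grid <= 14.0))
    coef = np.polyfit(np.log(grid[trend_mask]), np.log(posterior[trend_mask] + 1e-30), 1)
    trend = np.exp(np.polyval(coef, np.log(grid)))
    band = (grid >= ALPHA_BAND[0]) & (grid <= ALPHA_BAND[1])
    idx = np.flatnonzero(band)
    best: float | None = None
    best_power = -np.inf
    for i in idx:
        lo = posterior[i - 1] if i > 0 else -np.inf
        hi = posterior[i + 1] if i + 1 < len(grid) else -np.inf
        is_local_max = posterior[i] >= lo and posterior[i] >= hi
        if is_local_max and posterior[i] > PEAK_PROMINENCE_FACTOR * trend[i]:
            if posterior[i] > best_power:
                best_power = posterior[i]
                best = float(grid[i])
    return best


def _spectrum(rec: Recording) -> tuple[np.ndarray, np.ndarray]:
    if rec.duration < 60.0:
        raise ValueError("resting recording must be at least 60 s")
    ep = _preprocess_epochs(_epochs(rec), rec.fs)
    freqs, psd = _multitaper_power(ep, rec.fs)
    power = _power_on_grid(freqs, psd)
    posterior = montage.posterior_channels(rec.channel_names)
    if posterior:
        pidx = [rec.channel_names.index(c) for c in posterior]
    else:
        pidx = list(range(rec.n_channels))
    return power, power[pidx].mean(axis=0)


def estimate_iaf(rec_open: Recording, rec_closed: Recording) -> SpectrumResult:
    """Estimate the individual alpha frequency with eyes-closed fallback."""
    power_open, post_open = _spectrum(rec_open)
    peak = _pick_peak(post_open)
    if peak is not None:
        return SpectrumResult(FREQ_GRID.copy(), power_open, post_open, peak,
                              "eyes_open", list(rec_open.channel_names))
    power_closed, post_closed = _spectrum(rec_closed)
    peak = _pick_peak(post_closed)
    if peak is not None:
        return SpectrumResult(FREQ_GRID.copy(), power_closed, post_closed, peak,
                              "eyes_closed", list(rec_closed.channel_names))
    return SpectrumResult(FREQ_GRID.copy(), power_closed, post_closed, None,
                          None, list(rec_closed.channel_names))
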