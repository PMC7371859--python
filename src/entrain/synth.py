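"""Ground-truth EEG session generator.

Produces continuous recordings with the statistical structure the analysis
pipeline assumes: a posterior alpha oscillator over 1/f background noise,
pulse-train coupling of tunable strength, TMS ringing and decay artifacts,
ocular blinks and bad channels.  Every generator is deterministic per seed.

Entrainment model: the alpha oscillator free-runs as a noisy phase
(constant drift at the configured alpha frequency plus Brownian phase
diffusion).  At each pulse of a *rhythmic* burst the oscillator phase is
redrawn from a von Mises distribution centered on the phase of the
offset-aligned reference wave, with concentration ``entrain_strength``
(kappa).  kappa = 0 reduces to a uniform redraw, making the phase
statistically independent of the pulse train; kappa -> inf locks it
perfectly.  Arrhythmic and sham bursts never couple to the oscillator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from . import montage
from .core_io import Event, Recording
from .protocol import PulseSchedule


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic EEG generator (amplitudes in microvolts)."""

    n_channels: int = 64
    fs: float = 2500.0
    iaf: float = 10.0
    alpha_amp: float = 20.0
    noise_exponent: float = 1.0
    noise_amp: float = 10.0
    entrain_strength: float = 0.0  # von Mises kappa
    ringing_amp: float = 1000.0
    decay_amp: float = 50.0
    decay_tau: float = 30.0  # ms
    blink_rate: float = 6.0  # events / minute
    bad_channels: tuple[str, ...] = ()
    seed: int = 0
    phase_diffusion: float = 4.0  # rad^2 / s
    closed_open_alpha_ratio: float = 2.0
    sham_transient_amp: float = 15.0
    harmonic_ratio: float = 0.25  # relative amplitude of the 2f component

    def __post_init__(self) -> None:
        if self.entrain_strength < 0:
            raise ValueError("entrain_strength (kappa) must be >= 0")
        if self.alpha_amp < 0 or self.noise_amp < 0:
            raise ValueError("amplitudes must be >= 0")
        if not 1 <= self.n_channels <= 64:
            raise ValueError("n_channels must be in 1..64")


@dataclass
class GroundTruth:
    """Injected structure of a synthetic recording, for parameter recovery."""

    oscillator_phase: np.ndarray  # unwrapped radians, per sample
    events: list[Event]
    blink_trace: np.ndarray       # unit source time courses (pre-topography)
    decay_trace: np.ndarray
    ringing_trace: np.ndarray
    alpha_topography: np.ndarray
    channel_names: list[str]
    fs: float


def _pick_channels(n_channels: int) -> tuple[list[str], np.ndarray]:
    labels, pos = montage.standard_64()
    if n_channels == 64:
        return labels, pos
    if n_channels == 32:
        idx = [labels.index(c) for c in montage.STANDARD_32]
    else:
        idx = sorted(set(np.linspace(0, 63, n_channels).round().astype(int)))
        while len(idx) < n_channels:  # fill collisions with unused indices
            idx.append(next(i for i in range(64) if i not in idx))
            idx = sorted(idx)
    return [labels[i] for i in idx], pos[idx]


def _alpha_topography(labels: list[str], pos: np.ndarray) -> np.ndarray:
    """Per-channel gain, Gaussian around the PO3 stimulation target."""
    full_labels, full_pos = montage.standard_64()
    center = full_pos[full_labels.index("PO3")]
    d = np.linalg.norm(pos - center, axis=1)
    return np.exp(-(d ** 2) / (2 * 0.55 ** 2))


def _frontal_topography(labels: list[str], pos: np.ndarray) -> np.ndarray:
    full_labels, full_pos = montage.standard_64()
    center = full_pos[full_labels.index("Fp1")] + full_pos[full_labels.index("Fp2")]
    center /= np.linalg.norm(center)
    d = np.linalg.norm(pos - center, axis=1)
    return np.exp(-(d ** 2) / (2 * 0.4 ** 2))


def _one_over_f_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                      fs: float, exponent: float) -> np.ndarray:
    """Unit-variance 1/f^exponent noise via spectral shaping of white noise."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = np.ones_like(freqs)
    nonzero = freqs > 0
    shape[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC drift
    out = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    out /= out.std(axis=1, keepdims=True) + 1e-30
    return out


def _blink_waveform(fs: float) -> np.ndarray:
    """400 ms biphasic blink template, peak amplitude 1."""
    t = np.arange(int(round(0.4 * fs))) / fs
    w = np.exp(-((t - 0.13) ** 2) / (2 * 0.045 ** 2)) \
        - 0.35 * np.exp(-((t - 0.26) ** 2) / (2 * 0.07 ** 2))
    return w / np.abs(w).max()


def _ringing_kernel(fs: float) -> np.ndarray:
    """Damped high-frequency transient confined to [-4, +9] ms around a pulse.

    Returned kernel covers sample offsets -round(4ms*fs) .. +round(9ms*fs)
    inclusive and is exactly zero outside.
    """
    pre = int(round(0.004 * fs))
    post = int(round(0.009 * fs))
    t = np.arange(-pre, post + 1) / fs
    f_ring = min(900.0, fs / 3.0)
    w = np.sin(2 * np.pi * f_ring * (t + 0.004)) * np.exp(-(t + 0.004) / 0.0025)
    # taper so the transient dies out strictly inside the window
    edge = np.hanning(2 * len(t))[len(t):] if len(t) > 2 else np.ones_like(t)
    w = w * edge
    peak = np.abs(w).max()
    return w / peak if peak > 0 else w


def _events_from_schedule(schedule: PulseSchedule, fs: float) -> list[Event]:
    """Schedule -> event list, with times snapped to the sample grid.

    Snapping keeps the excision masks computed downstream (in trial time)
    aligned with the artifact samples injected here (in recording time).
    """
    def snap(t: float) -> float:
        return round(t * fs) / fs

    events: list[Event] = []
    n_blocks = len(schedule.block_structure)
    per_block = schedule.n_bursts // n_blocks if n_blocks else 0
    for j, (cond, times) in enumerate(schedule.bursts):
        if per_block and j % per_block == 0:
            events.append(Event(snap(times[0]) - 0.5, "block_start", cond, j))
        events.append(Event(snap(times[0]), "burst_onset", cond, j))
        events.extend(Event(snap(t), "pulse", cond, j) for t in times)
        events.append(Event(snap(times[-1]), "burst_offset", cond, j))
        if per_block and (j + 1) % per_block == 0:
            events.append(Event(snap(times[-1]) + 0.5, "block_end", cond, j))
    return sorted(events, key=lambda e: (e.time, e.kind != "block_start"))


def _oscillator_phase(rng: np.random.Generator, cfg: SynthConfig, n: int,
                      pulse_samples: np.ndarray, target_phases: np.ndarray) -> np.ndarray:
    """Noisy phase ramp with von Mises redraws at coupled pulse samples."""
    dt = 1.0 / cfg.fs
    inc = np.full(n, 2 * np.pi * cfg.iaf * dt)
    inc += np.sqrt(cfg.phase_diffusion * dt) * rng.standard_normal(n)
    inc[0] = rng.uniform(-np.pi, np.pi)
    phase = np.cumsum(inc)
    if len(pulse_samples):
        drawn = rng.vonmises(target_phases, cfg.entrain_strength)
        corr = np.zeros(n)
        c_cum = 0.0
        for i, phi_star in zip(pulse_samples, drawn):
            c = phi_star - (phase[i] + c_cum)
            c_cum += c
            corr[i] += c
        phase += np.cumsum(corr)
    return phase


def _render(cfg: SynthConfig, n_samples: int,
            schedule: PulseSchedule | None,
            sham: bool, blinks: bool,
            alpha_scale: float = 1.0) -> tuple[Recording, GroundTruth]:
    labels, pos = _pick_channels(cfg.n_channels)
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    n = n_samples

    topo = _alpha_topography(labels, pos)
    events = _events_from_schedule(schedule, fs) if schedule is not None else []

    # coupled pulses: rhythmic bursts only, and never for sham or phantom
    pulse_samples = np.array([], dtype=int)
    target_phases = np.array([])
    if schedule is not None and not sham:
        coupled = []
        targets = []
        for cond, times in schedule.bursts:
            if cond != "rhythmic":
                continue
            offset = times[-1]
            for t in times:
                coupled.append(int(round(t * fs)))
                targets.append(2 * np.pi * cfg.iaf * (t - offset))
        pulse_samples = np.asarray(coupled, dtype=int)
        target_phases = np.asarray(targets)

    phase = _oscillator_phase(rng, cfg, n, pulse_samples, target_phases)
    # mildly non-sinusoidal waveform so entrainment shows up at 2f as well
    wave = np.cos(phase) + cfg.harmonic_ratio * np.cos(2 * phase)
    data = (alpha_scale * cfg.alpha_amp) * topo[:, None] * wave[None, :]
    # volume-conduction-like spatial correlation: mix neighboring channels'
    # noise so that nearby sensors are substantially correlated
    noise = _one_over_f_noise(rng, len(labels), n, fs, cfg.noise_exponent)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    mix = np.exp(-(d ** 2) / (2 * 0.35 ** 2))
    mix /= np.linalg.norm(mix, axis=1, keepdims=True)
    data += cfg.noise_amp * (mix @ noise)

    ringing_trace = np.zeros(n)
    decay_trace = np.zeros(n)
    blink_trace = np.zeros(n)

    if schedule is not None and not sham:
        all_pulses = np.concatenate([t for _, t in schedule.bursts])
        pulse_idx = np.round(all_pulses * fs).astype(int)
        if cfg.ringing_amp > 0:
            kernel = _ringing_kernel(fs)
            pre = int(round(0.004 * fs))
            gains = 0.6 + 0.8 * rng.random(len(labels))
            for ip in pulse_idx:
                lo, hi = ip - pre, ip - pre + len(kernel)
                if 0 <= lo and hi <= n:
                    ringing_trace[lo:hi] += kernel
            data += cfg.ringing_amp * gains[:, None] * ringing_trace[None, :]
        if cfg.decay_amp > 0:
            tau = cfg.decay_tau / 1000.0
            decay_kernel = np.exp(-np.arange(int(round(8 * tau * fs))) / (tau * fs))
            w = rng.standard_normal(len(labels))
            w /= np.abs(w).max()
            for ip in pulse_idx:
                hi = min(ip + len(decay_kernel), n)
                if ip < n:
                    decay_trace[ip:hi] += decay_kernel[:hi - ip]
            data += cfg.decay_amp * w[:, None] * decay_trace[None, :]

    if sham and schedule is not None:
        # auditory-evoked-like transient: theta-alpha burst over temporal
        # channels, decaying within the first five pulses of each burst
        temporal = [i for i, c in enumerate(labels) if c in montage.TEMPORAL_CHANNELS]
        if not temporal:
            temporal = list(np.argsort(-np.abs(pos[:, 0]))[:2])
        tgain = np.zeros(len(labels))
        for i in temporal:
            tgain[i] = 1.0
        burst_len = int(round(0.15 * fs))
        tt = np.arange(burst_len) / fs
        wave = np.sin(2 * np.pi * 6.0 * tt) + 0.6 * np.sin(2 * np.pi * cfg.iaf * tt)
        wave *= np.hanning(burst_len)
        for cond, times in schedule.bursts:
            for k, t in enumerate(times[:5]):
                ip = int(round(t * fs))
                hi = min(ip + burst_len, n)
                if ip < n:
                    seg = cfg.sham_transient_amp * np.exp(-k / 1.5) * wave[:hi - ip]
                    data[temporal, ip:hi] += seg[None, :]

    if blinks and cfg.blink_rate > 0:
        wave = _blink_waveform(fs)
        n_blinks = rng.poisson(cfg.blink_rate * (n / fs) / 60.0)
        starts = rng.integers(0, max(n - len(wave), 1), size=n_blinks)
        for s in np.sort(starts):
            blink_trace[s:s + len(wave)] += wave[:max(n - s, 0)][:len(wave)]
        ftopo = _frontal_topography(labels, pos)
        data += 80.0 * ftopo[:, None] * blink_trace[None, :]

    for bad in cfg.bad_channels:
        if bad in labels:
            i = labels.index(bad)
            data[i] += 10.0 * max(cfg.noise_amp, 1.0) * rng.standard_normal(n)

    rec = Recording(data, fs, list(labels), pos, events,
                    meta={"generator": "entrain.synth", "seed": cfg.seed})
    gt = GroundTruth(phase, events, blink_trace, decay_trace, ringing_trace,
                     topo, list(labels), fs)
    return rec, gt


def generate_session(cfg: SynthConfig, schedule: PulseSchedule,
                     tail: float = 6.0) -> tuple[Recording, GroundTruth]:
    """Full stimulation session (rhythmic/arrhythmic bursts with artifacts)."""
    n = int(round((schedule.end_time + tail) * cfg.fs))
    sham = all(c == "sham" for c in schedule.conditions())
    return _render(cfg, n, schedule, sham=sham, blinks=True)


def generate_resting(cfg: SynthConfig, duration: float,
                     eyes: Literal["open", "closed"] = "open"
                     ) -> tuple[Recording, GroundTruth]:
    """Resting-state recording: no pulses; blinks only with eyes open."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * cfg.fs))
    scale = cfg.closed_open_alpha_ratio if eyes == "closed" else 1.0
    return _render(cfg, n, schedule=None, sham=False,
                   blinks=(eyes == "open"), alpha_scale=scale)


def generate_phantom(cfg: SynthConfig, schedule: PulseSchedule,
                     n_channels: int = 32, tail: float = 6.0) -> Recording:
    """Phantom ('piece of meat') run: artifacts and noise, no alpha source."""
    pcfg = replace(cfg, alpha_amp=0.0, n_channels=n_channels,
                   blink_rate=0.0, entrain_strength=0.0)
    n = int(round((schedule.end_time + tail) * pcfg.fs))
    rec, _ = _render(pcfg, n, schedule, sham=False, blinks=False)
    return rec


def simulate_pulse_markers(rec: Recording, iaf: float, n_pulses: int = 20,
                           n_bursts: int = 25, interburst: float = 10.0,
                           lead_in: float = 4.0) -> Recording:
    """Add periodic simulated-pulse markers to a pulse-free recording.

    Data samples are left untouched; excision and interpolation of the
    marked windows happen downstream in preprocessing.
    """
    if rec.events_of("pulse"):
        raise ValueError("recording already contains pulse events")
    burst_dur = n_pulses / iaf
    needed = lead_in + n_bursts * burst_dur + (n_bursts - 1) * interburst + 5.0
    if needed > rec.duration:
        raise ValueError(f"recording too short: need {needed:.1f} s, "
                         f"have {rec.duration:.1f} s")
    events = list(rec.events)
    t = lead_in
    for j in range(n_bursts):
        times = t + np.arange(n_pulses) / iaf
        events.append(Event(float(times[0]), "burst_onset", "rhythmic", j))
        events.extend(Event(float(tt), "pulse", "rhythmic", j) for tt in times)
        events.append(Event(float(times[-1]), "burst_offset", "rhythmic", j))
        t += burst_dur + interburst
    return replace(rec, events=sorted(events, key=lambda e: e.time))


def sham_schedule(iaf: float, n_bursts: int = 25, n_pulses: int = 20,
                  interburst_choices: tuple[float, ...] = (10.0, 11.0),
                  lead_in: float = 4.0, seed: int = 0) -> PulseSchedule:
    """Rhythmic-timing schedule labeled 'sham' (coil tilted, no EF coupling)."""
    rng = np.random.default_rng(seed)
    bursts = []
    t = lead_in
    for _ in range(n_bursts):
        rel = np.arange(n_pulses) / iaf
        bursts.append(("sham", t + rel))
        t += n_pulses / iaf + float(rng.choice(interburst_choices))
    return PulseSchedule(bursts, iaf, n_pulses, block_structure=["sham"], seed=seed)
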