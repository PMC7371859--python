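"""TMS-EEG artifact removal: continuous Recording -> clean TrialSet.

Stage order is fixed: segment -> excise ringing -> decay ICA ->
pchip interpolation -> common-average re-reference + downsample ->
trial/channel rejection -> ocular ICA.  Every stage appends to the
TrialSet log so rejection counts are auditable.

Units are microvolts throughout; trial time is seconds relative to the
burst offset (t = 0 at the last pulse of the burst).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import decimate, welch
from sklearn.decomposition import FastICA

from . import montage
from .core_io import NeighborGraph, Recording

TRIAL_PRE = 3.5   # s before burst offset
TRIAL_POST = 5.0  # s after burst offset
RING_PRE = 0.004  # s before each pulse
RING_POST = 0.009  # s after each pulse
DECAY_CRITERION_UV = 30.0
DECAY_WINDOW = 0.050  # s after pulse for the decay criterion
STD_CRITERION_UV = 30.0
CORR_CRITERION = 0.4
IQR_FACTOR = 1.5
BAD_CHANNEL_FRACTION = 0.2
TARGET_FS = 1250.0


@dataclass
class TrialSet:
    """Epoched EEG: trials x channels x samples with per-sample validity."""

    data: np.ndarray            # (n_trials, n_channels, n_samples), uV
    fs: float
    times: np.ndarray           # (n_samples,), s relative to burst offset
    valid: np.ndarray           # boolean, same shape as data's last axes
    conditions: list[str]       # per trial
    pulse_times: list[np.ndarray]  # per trial, s relative to burst offset
    channel_names: list[str]
    positions: np.ndarray | None = None
    log: list[str] = field(default_factory=list)
    interpolated_channels: set[str] = field(default_factory=set)
    trial_indices: list[int] = field(default_factory=list)  # provenance

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, names: list[str]) -> list[int]:
        return [self.channel_names.index(n) for n in names]

    def select_conditions(self, *conditions: str) -> "TrialSet":
        keep = [i for i, c in enumerate(self.conditions) if c in conditions]
        idx = self.trial_indices or list(range(self.n_trials))
        return replace(
            self, data=self.data[keep], valid=self.valid[keep],
            conditions=[self.conditions[i] for i in keep],
            pulse_times=[self.pulse_times[i] for i in keep], log=list(self.log),
            trial_indices=[idx[i] for i in keep],
        )


@dataclass
class Decomposition:
    """ICA mixing/unmixing with per-component rejection bookkeeping."""

    mixing: np.ndarray      # (n_channels, n_components)
    unmixing: np.ndarray    # (n_components, n_channels)
    mean: np.ndarray        # channel means removed before unmixing
    rejected: list[int]
    reasons: dict[int, str]


def segment_trials(rec: Recording) -> TrialSet:
    """One trial per burst offset, spanning -3.5 .. +5.0 s around it."""
    offsets = rec.events_of("burst_offset")
    if not offsets:
        raise ValueError("recording contains no burst_offset events")
    n_samp = int(round((TRIAL_PRE + TRIAL_POST) * rec.fs))
    times = -TRIAL_PRE + np.arange(n_samp) / rec.fs
    pulses = rec.events_of("pulse")

    data, conds, ptimes = [], [], []
    log = []
    for ev in offsets:
        start = int(round((ev.time - TRIAL_PRE) * rec.fs))
        if start < 0 or start + n_samp > rec.n_samples:
            log.append(f"segment: dropped burst {ev.burst_index} (window out of bounds)")
            warnings.warn(f"burst {ev.burst_index}: trial window exceeds recording")
            continue
        data.append(rec.data[:, start:start + n_samp])
        conds.append(ev.condition)
        ptimes.append(np.array(sorted(
            p.time - ev.time for p in pulses if p.burst_index == ev.burst_index)))
    if not data:
        raise ValueError("no trial fits within the recording bounds")
    arr = np.stack(data)
    log.append(f"segment: {len(data)} trials of {TRIAL_PRE + TRIAL_POST} s")
    return TrialSet(arr, rec.fs, times, np.ones(arr.shape, dtype=bool),
                    conds, ptimes, list(rec.channel_names), rec.positions, log,
                    trial_indices=list(range(len(data))))


def _ringing_mask(ts: TrialSet, trial: int) -> np.ndarray:
    """Boolean mask of samples inside any [-4, +9] ms pulse window."""
    mask = np.zeros(ts.n_samples, dtype=bool)
    fs = ts.fs
    for tp in ts.pulse_times[trial]:
        lo = int(np.ceil((tp - RING_PRE + TRIAL_PRE) * fs - 1e-9))
        hi = int(np.floor((tp + RING_POST + TRIAL_PRE) * fs + 1e-9))
        mask[max(lo, 0):min(hi, ts.n_samples - 1) + 1] = True
    return mask


def excise_ringing(ts: TrialSet) -> TrialSet:
    """Mark [-4, +9] ms around every pulse invalid on all channels."""
    valid = ts.valid.copy()
    total = 0
    for i in range(ts.n_trials):
        mask = _ringing_mask(ts, i)
        valid[i, :, mask.nonzero()[0]] = False
        total += int(mask.sum())
    log = ts.log + [f"excise_ringing: masked {total} samples/channel-row total"]
    return replace(ts, valid=valid, log=log)


def _fit_ica(x: np.ndarray, n_components: int, seed: int = 0,
             max_attempts: int = 3) -> FastICA:
    last_err: Exception | None = None
    for attempt in range(max_attempts):
        ica = FastICA(n_components=n_components, whiten="unit-variance",
                      random_state=seed + attempt, max_iter=500, tol=1e-4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                ica.fit(x)
                return ica
            except Exception as exc:  # pragma: no cover - rare non-convergence
                last_err = exc
    raise RuntimeError(f"ICA failed after {max_attempts} attempts") from last_err


def remove_decay_components(ts: TrialSet, n_components: int | None = None,
                            seed: int = 0) -> tuple[TrialSet, Decomposition]:
    """Reject ICA components whose pulse-averaged post-pulse course > 30 uV.

    The ICA is fit on valid (non-ringing) samples only.  The criterion is
    the maximum absolute value of the trial-averaged component time course
    within (9, 50] ms after any pulse, expressed in microvolts at the
    component's strongest channel.
    """
    if n_components is None:
        n_components = min(ts.n_channels - 1, 63)
    valid_cols = ts.valid.all(axis=1)  # (trials, samples): sample valid on all ch
    x_fit = np.concatenate(
        [ts.data[i][:, valid_cols[i]] for i in range(ts.n_trials)], axis=1)
    ica = _fit_ica(x_fit.T, n_components, seed)
    mixing = ica.mixing_                       # (channels, comps)
    unmixing = ica.components_                 # (comps, channels)
    mean = ica.mean_

    # full component time courses (masked samples included; the criterion
    # window starts after the excised ringing interval anyway)
    flat = ts.data.transpose(1, 0, 2).reshape(ts.n_channels, -1)
    sources = unmixing @ (flat - mean[:, None])
    sources = sources.reshape(n_components, ts.n_trials, ts.n_samples)

    # pulse-locked averaging: epoch each component around every pulse of
    # every trial and average, so that windows stay aligned even when pulse
    # times differ across trials (arrhythmic bursts)
    lo_off = int(np.floor(RING_POST * ts.fs)) + 1
    hi_off = int(np.floor(DECAY_WINDOW * ts.fs))
    win_len = hi_off - lo_off + 1
    epochs = []
    for i in range(ts.n_trials):
        for tp in ts.pulse_times[i]:
            ip = int(round((tp + TRIAL_PRE) * ts.fs))
            lo, hi = ip + lo_off, ip + hi_off + 1
            if 0 <= lo and hi <= ts.n_samples:
                epochs.append(sources[:, i, lo:hi])
    scale = np.abs(mixing).max(axis=0)         # uV per source unit, strongest ch
    if not epochs:
        criterion = np.zeros(n_components)
    else:
        pulse_avg = np.mean(epochs, axis=0)    # (comps, win_len)
        criterion = np.abs(pulse_avg).max(axis=1) * scale

    rejected = [int(k) for k in np.flatnonzero(criterion > DECAY_CRITERION_UV)]
    keep = [k for k in range(n_components) if k not in rejected]
    if keep:
        recon = mixing[:, keep] @ sources[keep].reshape(
            len(keep), ts.n_trials * ts.n_samples) + mean[:, None]
    else:  # degenerate: everything looked like decay; keep only the mean
        recon = np.broadcast_to(mean[:, None],
                                (ts.n_channels, ts.n_trials * ts.n_samples)).copy()
    data = recon.reshape(ts.n_channels, ts.n_trials, ts.n_samples).transpose(1, 0, 2)
    dec = Decomposition(mixing, unmixing, mean, rejected,
                        {k: f"decay criterion {criterion[k]:.1f} uV" for k in rejected})
    log = ts.log + [f"decay_ica: rejected {len(rejected)}/{n_components} components"]
    return replace(ts, data=data, log=log), dec


def interpolate_gaps(ts: TrialSet) -> TrialSet:
    """Replace masked samples by shape-preserving pchip; clears the mask."""
    data = ts.data.copy()
    idx = np.arange(ts.n_samples)
    for i in range(ts.n_trials):
        col_valid = ts.valid[i].all(axis=0)
        if col_valid.all():
            continue
        gaps = ~col_valid
        for c in range(ts.n_channels):
            good = idx[col_valid]
            if len(good) < 4:
                raise ValueError("not enough valid samples to interpolate")
            interp = PchipInterpolator(good, data[i, c, col_valid], extrapolate=False)
            filled = interp(idx[gaps])
            # nearest-value extension for gaps touching the trial edges
            nan = np.isnan(filled)
            if nan.any():
                filled[nan] = np.interp(idx[gaps][nan], good, data[i, c, col_valid])
            data[i, c, gaps] = filled
    log = ts.log + ["interpolate: pchip-filled masked windows"]
    return replace(ts, data=data, valid=np.ones_like(ts.valid), log=log)


def rereference_downsample(ts: TrialSet, target_fs: float = TARGET_FS) -> TrialSet:
    """Common-average re-reference, then anti-aliased decimation."""
    factor = ts.fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"fs {ts.fs} not an integer multiple of {target_fs}")
    q = int(round(factor))
    data = ts.data - ts.data.mean(axis=1, keepdims=True)
    if q > 1:
        data = decimate(data, q, axis=2, ftype="fir", zero_phase=True)
        times = ts.times[::q][:data.shape[2]]
        valid = ts.valid[:, :, ::q][:, :, :data.shape[2]]
    else:
        times, valid = ts.times, ts.valid
    log = ts.log + [f"rereference_downsample: CAR, {ts.fs:g} -> {target_fs:g} Hz"]
    return replace(ts, data=data, fs=target_fs, times=times, valid=valid, log=log)


def _neighbor_weights(nb: NeighborGraph, positions: np.ndarray,
                      target: int, donors: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(positions[donors] - positions[target], axis=1)
    w = 1.0 / np.maximum(d, 1e-12)
    return w / w.sum()


def reject_artifacts(ts: TrialSet, nb: NeighborGraph) -> TrialSet:
    """IQR power outliers, STD > 30 uV and low neighbor correlation rules."""
    if tuple(nb.channel_names) != tuple(ts.channel_names):
        raise ValueError("neighbor graph does not cover the trial channels")
    if ts.positions is None:
        raise ValueError("channel positions required for neighbor interpolation")
    data = ts.data.copy()
    log = list(ts.log)
    interpolated = set(ts.interpolated_channels)

    # (1) per-trial/channel broadband power; the IQR fence is computed per
    # channel across trials so that topography differences (posterior alpha)
    # are not themselves treated as outliers
    power = (data ** 2).mean(axis=2)
    q1, q3 = np.percentile(power, [25, 75], axis=0)
    iqr = q3 - q1
    bad_cells = (power > q3 + IQR_FACTOR * iqr) | (power < q1 - IQR_FACTOR * iqr)
    keep_trials = []
    n_cell_interp = 0
    for i in range(ts.n_trials):
        bad = np.flatnonzero(bad_cells[i])
        if len(bad) >= BAD_CHANNEL_FRACTION * ts.n_channels:
            log.append(f"reject: trial {i} removed ({len(bad)}/{ts.n_channels} bad)")
            continue
        for c in bad:
            donors = np.array([j for j in nb.neighbors(c) if not bad_cells[i, j]])
            if len(donors) == 0:
                donors = np.array([j for j in range(ts.n_channels)
                                   if j != c and not bad_cells[i, j]])
            w = _neighbor_weights(nb, ts.positions, c, donors)
            data[i, c] = w @ data[i, donors]
            n_cell_interp += 1
        keep_trials.append(i)
    if n_cell_interp:
        log.append(f"reject: interpolated {n_cell_interp} trial-channel cells")
    data = data[keep_trials]
    conds = [ts.conditions[i] for i in keep_trials]
    ptimes = [ts.pulse_times[i] for i in keep_trials]
    valid = ts.valid[keep_trials]
    src_idx = ts.trial_indices or list(range(ts.n_trials))
    tidx = [src_idx[i] for i in keep_trials]

    # (2) whole-channel STD rule, (3) neighbor-correlation rule
    flat = data.transpose(1, 0, 2).reshape(ts.n_channels, -1)
    bad_channels = set(np.flatnonzero(flat.std(axis=1) > STD_CRITERION_UV).tolist())
    corr = np.corrcoef(flat)
    for c in range(ts.n_channels):
        neigh = [j for j in nb.neighbors(c) if j not in bad_channels]
        if neigh and np.nanmean(corr[c, neigh]) < CORR_CRITERION:
            bad_channels.add(c)
    if len(bad_channels) > 0.5 * ts.n_channels:
        raise RuntimeError("more than half of the channels are bad; data unusable")
    for c in sorted(bad_channels):
        donors = np.array([j for j in nb.neighbors(c) if j not in bad_channels])
        if len(donors) == 0:
            donors = np.array([j for j in range(ts.n_channels) if j not in bad_channels])
        w = _neighbor_weights(nb, ts.positions, c, donors)
        data[:, c, :] = np.einsum("j,tjs->ts", w, data[:, donors, :])
        interpolated.add(ts.channel_names[c])
        log.append(f"reject: channel {ts.channel_names[c]} removed and interpolated")
    log.append(f"reject: kept {len(keep_trials)}/{ts.n_trials} trials, "
               f"{len(bad_channels)} channels interpolated")
    return replace(ts, data=data, valid=valid, conditions=conds,
                   pulse_times=ptimes, log=log, interpolated_channels=interpolated,
                   trial_indices=tidx)


def remove_ocular_components(ts: TrialSet, seed: int = 0
                             ) -> tuple[TrialSet, Decomposition]:
    """Second ICA pass; removes blink/saccade-like components.

    A component is flagged if |r| > 0.7 against a virtual EOG (mean of the
    frontal Fp/AF channels), or if its topography is strongly frontal
    (frontal/posterior loading ratio > 3) with dominant power below 5 Hz and
    at least moderate vEOG correlation (|r| > 0.3).
    """
    n_components = max(min(ts.n_channels - 1 - len(ts.interpolated_channels),
                           ts.n_channels - 1), 2)
    flat = ts.data.transpose(1, 0, 2).reshape(ts.n_channels, -1)
    ica = _fit_ica(flat.T, n_components, seed)
    sources = ica.components_ @ (flat - ica.mean_[:, None])

    frontal = ts.channel_index(
        [c for c in montage.frontal_channels(ts.channel_names)])
    posterior = ts.channel_index(
        [c for c in montage.posterior_channels(ts.channel_names)])
    veog = flat[frontal].mean(axis=0) if frontal else np.zeros(flat.shape[1])

    rejected: list[int] = []
    reasons: dict[int, str] = {}
    for k in range(n_components):
        r = 0.0
        if veog.std() > 0 and sources[k].std() > 0:
            r = float(np.corrcoef(sources[k], veog)[0, 1])
        if abs(r) > 0.7:
            rejected.append(k)
            reasons[k] = f"virtual EOG correlation {r:.2f}"
            continue
        load = np.abs(ica.mixing_[:, k])
        f_load = load[frontal].max() if frontal else 0.0
        p_load = load[posterior].max() if posterior else load.max()
        if p_load > 0 and f_load / p_load > 3.0 and abs(r) > 0.3:
            freqs, psd = welch(sources[k], fs=ts.fs, nperseg=min(len(sources[k]), 4096))
            if freqs[np.argmax(psd)] < 5.0:
                rejected.append(k)
                reasons[k] = (f"frontal topography ratio {f_load / p_load:.1f}, "
                              f"slow, EOG correlation {r:.2f}")
    keep = [k for k in range(n_components) if k not in rejected]
    recon = ica.mixing_[:, keep] @ sources[keep] + ica.mean_[:, None]
    data = recon.reshape(ts.n_channels, ts.n_trials, ts.n_samples).transpose(1, 0, 2)
    dec = Decomposition(ica.mixing_, ica.components_, ica.mean_, rejected, reasons)
    log = ts.log + [f"ocular_ica: rejected {len(rejected)}/{n_components} components"]
    return replace(ts, data=data, log=log), dec


def preprocess(rec: Recording, nb: NeighborGraph | None = None,
               target_fs: float | None = None, ica_seed: int = 0,
               decay_components: int | None = None) -> TrialSet:
    """Run the full cascade in the documented order."""
    from .core_io import build_neighbors

    if nb is None:
        if rec.positions is None:
            raise ValueError("recording has no positions; supply a NeighborGraph")
        nb = build_neighbors(rec.positions, channel_names=rec.channel_names)
    if target_fs is None:
        target_fs = TARGET_FS if (rec.fs / TARGET_FS).is_integer() else rec.fs
    ts = segment_trials(rec)
    ts = excise_ringing(ts)
    ts, _ = remove_decay_components(ts, decay_components, seed=ica_seed)
    ts = interpolate_gaps(ts)
    ts = rereference_downsample(ts, target_fs)
    ts = reject_artifacts(ts, nb)
    ts, _ = remove_ocular_components(ts, seed=ica_seed)
    return ts
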