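"""Stimulation protocol generation and dose arithmetic.

Rhythmic bursts place pulses at k / f for k = 0 .. n-1; the burst duration
follows the n / f convention (20 pulses at 8 Hz -> 2.5 s).  Arrhythmic
bursts draw each instantaneous frequency uniformly from [3, 30] Hz with the
alpha band, its first harmonic and its subharmonic excluded, and are
duration-matched to the rhythmic burst within +/-10% by rejection sampling.

Dose helpers assume a linear mapping between stimulator output (%MSO) and
induced electric field magnitude (mV/mm); the slope comes from an external
FEM run at a reference intensity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

SAMPLING_RANGE_HZ = (3.0, 30.0)


@dataclass(frozen=True)
class ForbiddenBands:
    """Frequency intervals excluded from arrhythmic inter-pulse intervals."""

    bands: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        for lo, hi in self.bands:
            if not lo < hi:
                raise ValueError(f"band ({lo}, {hi}) must have low < high")

    def contains(self, freq: float, tol: float = 1e-9) -> bool:
        """Band membership, inclusive of edges up to a small tolerance."""
        return any(lo - tol <= freq <= hi + tol for lo, hi in self.bands)


@dataclass
class PulseSchedule:
    """Per-burst pulse times with condition labels and block structure."""

    bursts: list[tuple[str, np.ndarray]]  # (condition, absolute pulse times s)
    stimulation_frequency: float
    n_pulses_per_burst: int
    block_structure: list[str] = field(default_factory=list)
    seed: int | None = None

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    def conditions(self) -> list[str]:
        return [c for c, _ in self.bursts]

    @property
    def end_time(self) -> float:
        return max(float(t[-1]) for _, t in self.bursts)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "stimulation_frequency": self.stimulation_frequency,
            "n_pulses_per_burst": self.n_pulses_per_burst,
            "block_structure": self.block_structure,
            "seed": self.seed,
            "bursts": [{"condition": c, "times": t.tolist()} for c, t in self.bursts],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PulseSchedule":
        payload = json.loads(Path(path).read_text())
        return cls(
            bursts=[(b["condition"], np.asarray(b["times"])) for b in payload["bursts"]],
            stimulation_frequency=payload["stimulation_frequency"],
            n_pulses_per_burst=payload["n_pulses_per_burst"],
            block_structure=payload["block_structure"],
            seed=payload["seed"],
        )


@dataclass(frozen=True)
class EFSummary:
    """Percentile summary of per-element electric-field magnitudes (mV/mm)."""

    mean: float
    median: float
    p2_5: float
    p97_5: float
    peak: float  # 99.9th percentile
    component: str = "absolute"


def rhythmic_burst(iaf: float, n_pulses: int = 20) -> tuple[np.ndarray, float]:
    """Pulse times k/iaf and burst duration n_pulses/iaf (seconds)."""
    if n_pulses < 2:
        raise ValueError("a burst needs at least 2 pulses")
    if not 8.0 <= iaf <= 12.0:
        warnings.warn(f"stimulation frequency {iaf} Hz outside the 8-12 Hz alpha range")
    times = np.arange(n_pulses) / iaf
    return times, n_pulses / iaf


def forbidden_bands(alpha_low: float = 8.0, alpha_high: float = 12.0) -> ForbiddenBands:
    """Alpha band plus its first harmonic and subharmonic bands."""
    if not 0 < alpha_low < alpha_high:
        raise ValueError("need 0 < alpha_low < alpha_high")
    return ForbiddenBands((
        (alpha_low / 2, alpha_high / 2),
        (alpha_low, alpha_high),
        (2 * alpha_low, 2 * alpha_high),
    ))


def _allowed_segments(bands: ForbiddenBands) -> list[tuple[float, float]]:
    lo, hi = SAMPLING_RANGE_HZ
    edges = sorted({lo, hi} | {b for band in bands.bands for b in band if lo < b < hi})
    segs = []
    for a, b in zip(edges[:-1], edges[1:]):
        if not bands.contains((a + b) / 2):
            segs.append((a, b))
    return segs


def arrhythmic_burst(iaf: float, n_pulses: int, bands: ForbiddenBands | None = None,
                     seed: int = 0, duration_tol: float = 0.10,
                     max_retries: int = 2000) -> np.ndarray:
    """Pulse times with every instantaneous frequency outside forbidden bands.

    The total burst duration is matched to the rhythmic burst at ``iaf``
    within ``duration_tol`` (relative) by rejection sampling; deterministic
    per seed.
    """
    if bands is None:
        bands = forbidden_bands()
    segs = _allowed_segments(bands)
    if not segs:
        raise ValueError("no allowed frequencies within the sampling range")
    widths = np.array([b - a for a, b in segs])
    probs = widths / widths.sum()
    target = n_pulses / iaf
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        which = rng.choice(len(segs), size=n_pulses - 1, p=probs)
        freqs = np.array([rng.uniform(*segs[w]) for w in which])
        intervals = 1.0 / freqs
        duration = intervals.sum() + 1.0 / iaf  # n/f convention: trailing period
        if abs(duration - target) <= duration_tol * target:
            return np.concatenate([[0.0], np.cumsum(intervals)])
    raise RuntimeError("could not satisfy the duration tolerance; relax duration_tol")


def schedule_session(iaf: float, n_blocks_per_condition: int = 5,
                     bursts_per_block: int = 25, n_pulses: int = 20,
                     conditions: tuple[str, ...] = ("rhythmic", "arrhythmic"),
                     interburst_choices: tuple[float, ...] = (10.0, 11.0),
                     lead_in: float = 4.0, seed: int = 0) -> PulseSchedule:
    """Full session: randomized block order, interburst gaps from {10, 11} s."""
    if n_blocks_per_condition < 1 or bursts_per_block < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    blocks = [c for c in conditions for _ in range(n_blocks_per_condition)]
    rng.shuffle(blocks)
    bursts: list[tuple[str, np.ndarray]] = []
    t = lead_in
    for cond in blocks:
        for _ in range(bursts_per_block):
            if cond == "arrhythmic":
                rel = arrhythmic_burst(iaf, n_pulses, seed=int(rng.integers(2**31)))
                dur = rel[-1] + 1.0 / iaf
            else:  # rhythmic and sham share the periodic timing
                rel, dur = rhythmic_burst(iaf, n_pulses)
            bursts.append((cond, t + rel))
            t += dur + float(rng.choice(interburst_choices))
    return PulseSchedule(bursts, iaf, n_pulses, block_structure=blocks, seed=seed)


def mso_for_target_ef(ef_target: float, ef_per_mso: float) -> float:
    """%MSO needed for a target field, under the linear EF(MSO) model."""
    if ef_per_mso <= 0:
        raise ValueError("ef_per_mso must be positive")
    return ef_target / ef_per_mso


def ef_for_mso(mso: float, ef_per_mso: float) -> float:
    """Field magnitude produced at the given %MSO (exact inverse of above)."""
    if ef_per_mso <= 0:
        raise ValueError("ef_per_mso must be positive")
    return mso * ef_per_mso


def intensity_as_rmt_pct(mso: float, rmt: float) -> float:
    """Express a stimulator output as percent of the resting motor threshold."""
    if rmt <= 0:
        raise ValueError("rmt must be positive")
    return 100.0 * mso / rmt


def summarize_ef(values: np.ndarray, component: str = "absolute") -> EFSummary:
    """Mean/median/2.5th/97.5th/99.9th ('peak') percentiles of EF magnitudes.

    Percentiles use linear interpolation between order statistics.  The
    monotone ordering invariant is only asserted for the absolute component;
    the normal component may legitimately contain negative values.
    """
    vals = np.asarray(values, dtype=float).ravel()
    if vals.size == 0:
        raise ValueError("empty EF table")
    p2_5, p97_5, peak = np.percentile(vals, [2.5, 97.5, 99.9], method="linear")
    summary = EFSummary(float(vals.mean()), float(np.median(vals)),
                        float(p2_5), float(p97_5), float(peak), component)
    if component == "absolute":
        assert summary.p2_5 <= summary.median <= summary.p97_5 <= summary.peak + 1e-12
    return summary
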