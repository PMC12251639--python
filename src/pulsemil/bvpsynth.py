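"""Synthetic blood-volume-pulse (BVP) session generator.

Real affective BVP corpora are access-restricted, so every downstream
stage of this package is exercised on synthetic sessions that emulate the
relevant physiology:

* a cardiac pulse train whose inter-beat intervals (IBIs) are modulated
  by sinusoids in the canonical HRV bands — HF (parasympathetic,
  0.15–0.4 Hz), LF (sympathetic/parasympathetic interplay, 0.04–0.15 Hz)
  and VLF (slow hormonal/thermoregulatory drift, < 0.04 Hz);
* transient high-arousal "events": a heart-rate surge plus a pulse
  amplitude gain confined to a sparse subset of 128-frame chunks,
  mimicking acute sympathetic bursts;
* additive white noise and sparse motion-artifact impulses;
* weak session-level labels: a session is labelled high-arousal iff it
  contains at least one event chunk, with 1–9 self-report-style ratings
  drawn from the matching half of the scale.

Each pulse is a two-lobe template: a systolic Gaussian plus a smaller,
delayed dicrotic Gaussian — the canonical PPG morphology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

CHUNK_LEN = 128
FS_DEFAULT = 30.0

# pulse template (unit systolic amplitude)
SYSTOLIC_SD_S = 0.060
DICROTIC_AMP = 0.35
DICROTIC_DELAY_S = 0.250
DICROTIC_SD_S = 0.060
ARTIFACT_AMP = 5.0
ARTIFACT_WIDTH = 3

# default IBI modulation: band centres of HF / LF / VLF
DEFAULT_BANDS = (
    (0.25, 0.03, 0.0),
    (0.10, 0.04, 0.0),
    (0.02, 0.05, 0.0),
)


@dataclass(frozen=True)
class ModulationBand:
    """One sinusoidal IBI modulation component.

    freq in Hz, amplitude in seconds of peak IBI deviation, phase in rad.
    """

    freq: float
    amplitude: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.freq <= 0.0:
            raise ValueError("band frequency must be positive")
        if self.amplitude < 0.0:
            raise ValueError("band amplitude must be nonnegative")


@dataclass(frozen=True)
class SyntheticSessionSpec:
    """Full description of one synthetic session."""

    duration_s: float
    hr_base: float = 60.0
    fs: float = FS_DEFAULT
    bands: tuple[ModulationBand, ...] = ()
    noise_sd: float = 0.05
    artifact_rate: float = 1.0  # impulses per minute
    event_chunks: frozenset[int] = frozenset()
    event_hr_surge: float = 20.0  # bpm added inside event chunks
    event_gain: float = 1.5  # pulse amplitude factor inside event chunks
    label_arousal: str = "low"
    label_valence: str = "low"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs != FS_DEFAULT:
            raise ValueError(f"sampling rate is fixed at {FS_DEFAULT} Hz")
        if not 30.0 <= self.hr_base <= 180.0:
            raise ValueError("hr_base must lie in [30, 180] bpm")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        n_chunks = self.n_chunks
        if any(c < 0 or c >= n_chunks for c in self.event_chunks):
            raise ValueError(f"event chunks must lie in [0, {n_chunks})")
        if (self.label_arousal == "high") != bool(self.event_chunks):
            raise ValueError("high arousal label must coincide with nonempty event set")
        min_ibi = 60.0 / (self.hr_base + (self.event_hr_surge if self.event_chunks else 0.0))
        if sum(b.amplitude for b in self.bands) >= min_ibi:
            raise ValueError("total modulation amplitude exceeds the baseline IBI")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    @property
    def n_chunks(self) -> int:
        return self.n_samples // CHUNK_LEN


def default_bands(rng: np.random.Generator | None = None) -> tuple[ModulationBand, ...]:
    """The three default HRV bands, optionally with random phases."""
    phases = rng.uniform(0.0, 2.0 * np.pi, size=3) if rng is not None else (0.0, 0.0, 0.0)
    return tuple(
        ModulationBand(freq=f, amplitude=a, phase=float(p))
        for (f, a, _), p in zip(DEFAULT_BANDS, phases)
    )


def _chunk_of(t: float, fs: float) -> int:
    return int(t * fs) // CHUNK_LEN


def generate_beat_times(spec: SyntheticSessionSpec) -> np.ndarray:
    """Beat onset times (s) of the modulated pulse train.

    The n-th IBI is ``60/hr + sum_b A_b sin(2 pi f_b t_n + phi_b)`` where
    ``hr`` is ``hr_base`` plus the event surge while the beat falls in an
    event chunk. Fully deterministic.
    """
    beats = []
    t = 0.0
    while t < spec.duration_s:
        beats.append(t)
        hr = spec.hr_base
        if _chunk_of(t, spec.fs) in spec.event_chunks:
            hr += spec.event_hr_surge
        ibi = 60.0 / hr
        for b in spec.bands:
            ibi += b.amplitude * np.sin(2.0 * np.pi * b.freq * t + b.phase)
        if ibi <= 0.0:
            raise ValueError("modulation produced a non-positive inter-beat interval")
        t += ibi
    return np.asarray(beats)


def render_waveform(beat_times: np.ndarray, spec: SyntheticSessionSpec) -> np.ndarray:
    """Render the 30 Hz BVP waveform from beat times.

    Each beat contributes a systolic Gaussian plus a delayed dicrotic
    Gaussian, scaled by ``event_gain`` inside event chunks; white noise
    and Poisson-placed artifact impulses are then added. Deterministic
    given ``spec.seed``.
    """
    n = spec.n_samples
    t_grid = np.arange(n) / spec.fs
    wave = np.zeros(n)
    half_window = DICROTIC_DELAY_S + 5.0 * DICROTIC_SD_S
    for tb in np.asarray(beat_times):
        if not 0.0 <= tb < spec.duration_s:
            raise ValueError("beat time outside the session duration")
        gain = spec.event_gain if _chunk_of(tb, spec.fs) in spec.event_chunks else 1.0
        lo = max(0, int((tb - 5.0 * SYSTOLIC_SD_S) * spec.fs))
        hi = min(n, int((tb + half_window) * spec.fs) + 1)
        dt = t_grid[lo:hi] - tb
        pulse = np.exp(-0.5 * (dt / SYSTOLIC_SD_S) ** 2)
        pulse += DICROTIC_AMP * np.exp(-0.5 * ((dt - DICROTIC_DELAY_S) / DICROTIC_SD_S) ** 2)
        wave[lo:hi] += gain * pulse
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        wave += rng.normal(0.0, spec.noise_sd, size=n)
    if spec.artifact_rate > 0:
        n_art = rng.poisson(spec.artifact_rate * spec.duration_s / 60.0)
        for _ in range(n_art):
            pos = rng.integers(0, max(1, n - ARTIFACT_WIDTH))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            wave[pos : pos + ARTIFACT_WIDTH] += sign * ARTIFACT_AMP
    return wave


def implant_saliency(spec: SyntheticSessionSpec) -> np.ndarray:
    """Per-chunk binary ground-truth mask: 1 where an event was implanted."""
    mask = np.zeros(spec.n_chunks, dtype=int)
    for c in spec.event_chunks:
        mask[c] = 1
    return mask


def generate_dataset(
    n_sessions: int,
    class_fraction_high: float = 0.5,
    event_count_range: tuple[int, int] = (2, 4),
    duration_s: float = 86.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    out_dir: str | Path | None = None,
    artifact_rate: float = 1.0,
    event_hr_surge: float = 20.0,
    event_gain: float = 1.5,
):
    """Generate a labelled synthetic dataset.

    Exactly ``round(n_sessions * class_fraction_high)`` sessions are
    high-arousal, each with a uniform number of event chunks drawn from
    ``event_count_range`` (inclusive); low-arousal sessions have none.
    Arousal ratings are integers from {5..9} for high and {1..4} for low
    sessions; valence ratings are uniform on 1–9 (no valence physiology
    is modelled). Returns ``(manifest, waveforms, masks)`` where
    ``waveforms`` and ``masks`` are dicts keyed by session id; if
    ``out_dir`` is given the sessions are also written in the package's
    CSV + JSON manifest dialect. Fully deterministic given ``seed``.
    """
    if n_sessions < 2:
        raise ValueError("need at least 2 sessions")
    if not 0.0 < class_fraction_high < 1.0:
        raise ValueError("class_fraction_high must lie in (0, 1)")
    lo_ev, hi_ev = event_count_range
    n_chunks = int(round(duration_s * FS_DEFAULT)) // CHUNK_LEN
    if hi_ev > n_chunks:
        raise ValueError(
            f"event_count_range upper bound {hi_ev} exceeds {n_chunks} chunks per session"
        )
    if lo_ev < 1 or lo_ev > hi_ev:
        raise ValueError("invalid event_count_range")

    rng = np.random.default_rng(seed)
    n_high = int(round(n_sessions * class_fraction_high))
    manifest: list[dict] = []
    waveforms: dict[str, np.ndarray] = {}
    masks: dict[str, list[int]] = {}
    for i in range(n_sessions):
        high = i < n_high
        sid = f"s{i:04d}"
        sess_seed = int(rng.integers(0, 2**31 - 1))
        hr = float(rng.uniform(55.0, 75.0))
        bands = default_bands(rng)
        if high:
            n_ev = int(rng.integers(lo_ev, hi_ev + 1))
            ev = frozenset(int(c) for c in rng.choice(n_chunks, size=n_ev, replace=False))
            rating_a = int(rng.integers(5, 10))
        else:
            ev = frozenset()
            rating_a = int(rng.integers(1, 5))
        rating_v = int(rng.integers(1, 10))
        spec = SyntheticSessionSpec(
            duration_s=duration_s,
            hr_base=hr,
            bands=bands,
            noise_sd=noise_sd,
            artifact_rate=artifact_rate,
            event_chunks=ev,
            event_hr_surge=event_hr_surge,
            event_gain=event_gain,
            label_arousal="high" if high else "low",
            label_valence="high" if rating_v >= 5 else "low",
            seed=sess_seed,
        )
        wave = render_waveform(generate_beat_times(spec), spec)
        waveforms[sid] = wave
        masks[sid] = [int(v) for v in implant_saliency(spec)]
        manifest.append(
            {
                "session_id": sid,
                "file": f"{sid}.csv",
                "fs": FS_DEFAULT,
                "n_samples": spec.n_samples,
                "rating_arousal": rating_a,
                "rating_valence": rating_v,
                "split": "unassigned",
                "seed": sess_seed,
            }
        )
    if out_dir is not None:
        write_dataset(out_dir, manifest, waveforms, masks)
    return manifest, waveforms, masks


def write_dataset(
    out_dir: str | Path,
    manifest: list[dict],
    waveforms: dict[str, np.ndarray],
    masks: dict[str, list[int]] | None = None,
) -> None:
    """Write waveform CSVs, ``manifest.json`` and optionally ``saliency.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import sessionio

    for entry in manifest:
        sessionio.write_waveform(out / entry["file"], waveforms[entry["session_id"]])
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    if masks is not None:
        (out / "saliency.json").write_text(json.dumps(masks, indent=1, sort_keys=True) + "\n")
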