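"""Session I/O, rating binarization, chunking and dataset splitting.

A *session* is a 30 Hz blood-volume-pulse waveform with 1–9 self-report
affect ratings (arousal, valence). On disk a dataset is a directory of
two-column CSV waveform files (``time_s,bvp``) plus a ``manifest.json``
listing per-session metadata, the dialect also produced by
:mod:`pulsemil.bvpsynth`.

Ratings are binarized at the scale midpoint (4.5): 1–4 -> low, 5–9 ->
high. Waveforms are cut into non-overlapping 128-frame chunks (~4 s at
30 Hz), the instance unit of the weakly supervised formulation; trailing
remainder frames are dropped. Sessions are split 80/10/10 at the session
level by a seeded shuffle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .bvpsynth import CHUNK_LEN, FS_DEFAULT

SPLITS = ("train", "val", "test", "unassigned")


@dataclass
class SessionRecord:
    session_id: str
    waveform: np.ndarray
    rating_arousal: int
    rating_valence: int
    split: str = "unassigned"
    fs: float = FS_DEFAULT

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        for r in (self.rating_arousal, self.rating_valence):
            _check_rating(r)
        if self.split not in SPLITS:
            raise ValueError(f"unknown split {self.split!r}")
        if not np.all(np.isfinite(self.waveform)):
            raise ValueError("waveform contains non-finite values")

    def label(self, target: str) -> str:
        if target == "arousal":
            return binarize_rating(self.rating_arousal)
        if target == "valence":
            return binarize_rating(self.rating_valence)
        raise ValueError(f"unknown target {target!r}")


@dataclass(frozen=True)
class ChunkSequence:
    session_id: str
    chunks: np.ndarray  # (T, 128)
    fs: float = FS_DEFAULT


def _check_rating(rating) -> int:
    if isinstance(rating, float) and not float(rating).is_integer():
        raise ValueError(f"ratings are integers on a 1-9 scale, got {rating}")
    r = int(rating)
    if r != rating or not 1 <= r <= 9:
        raise ValueError(f"rating must be an integer in [1, 9], got {rating}")
    return r


def binarize_rating(rating: int) -> str:
    """Binarize a 1–9 rating at the midpoint: <= 4 -> 'low', >= 5 -> 'high'."""
    r = _check_rating(rating)
    return "low" if r <= 4 else "high"


def chunk_waveform(
    waveform: np.ndarray, chunk_len: int = CHUNK_LEN, session_id: str = ""
) -> ChunkSequence:
    """Cut a waveform into non-overlapping ``chunk_len``-sample chunks.

    Chunk i covers samples [chunk_len*i, chunk_len*(i+1)); the trailing
    remainder is dropped. A waveform shorter than one chunk is an error.
    """
    w = np.asarray(waveform, dtype=float)
    if w.ndim != 1:
        raise ValueError("waveform must be 1-d")
    if w.size < chunk_len:
        raise ValueError(
            f"waveform has {w.size} samples; at least {chunk_len} are required"
        )
    t = w.size // chunk_len
    chunks = w[: t * chunk_len].reshape(t, chunk_len)
    return ChunkSequence(session_id=session_id, chunks=chunks)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_manifest(
    manifest: list[dict],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> list[dict]:
    """Assign train/val/test split tags by a seeded session-level shuffle.

    Val and test sizes are ``round(f * N)`` (half-up); train takes the
    remainder, so 527 sessions yield (421, 53, 53) under 80/10/10.
    Returns a new manifest list; input order is preserved.
    """
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be three values summing to 1")
    n = len(manifest)
    if n < 3:
        raise ValueError("need at least 3 sessions to split")
    n_val = _round_half_up(fractions[1] * n)
    n_test = _round_half_up(fractions[2] * n)
    n_train = n - n_val - n_test
    if n_train < 1:
        raise ValueError("split fractions leave no training sessions")
    ids = sorted(e["session_id"] for e in manifest)
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    assign = {}
    for sid in ids[:n_train]:
        assign[sid] = "train"
    for sid in ids[n_train : n_train + n_val]:
        assign[sid] = "val"
    for sid in ids[n_train + n_val :]:
        assign[sid] = "test"
    return [{**e, "split": assign[e["session_id"]]} for e in manifest]


# --------------------------------------------------------------------- files
def write_waveform(path: str | Path, waveform: np.ndarray) -> None:
    """Write a waveform as two-column CSV (time_s, bvp) at 30 Hz."""
    w = np.asarray(waveform, dtype=float)
    t = np.arange(w.size) / FS_DEFAULT
    lines = ["time_s,bvp"]
    lines += [f"{ti:.6f},{vi:.6f}" for ti, vi in zip(t, w)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_waveform(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"waveform file not found: {path}")
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    return np.atleast_2d(data)[:, 1].copy()


def write_session(directory: str | Path, record: SessionRecord) -> dict:
    """Write one session's waveform CSV and return its manifest entry."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fname = f"{record.session_id}.csv"
    write_waveform(directory / fname, record.waveform)
    return {
        "session_id": record.session_id,
        "file": fname,
        "fs": record.fs,
        "n_samples": int(record.waveform.size),
        "rating_arousal": record.rating_arousal,
        "rating_valence": record.rating_valence,
        "split": record.split,
        "seed": 0,
    }


def load_manifest(manifest_path: str | Path) -> list[dict]:
    path = Path(manifest_path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    return json.loads(path.read_text())


def save_manifest(manifest_path: str | Path, manifest: list[dict]) -> None:
    Path(manifest_path).write_text(json.dumps(manifest, indent=1) + "\n")


def load_session(directory: str | Path, entry: dict) -> SessionRecord:
    """Load one session from its manifest entry, checking consistency."""
    wave = read_waveform(Path(directory) / entry["file"])
    if wave.size != entry["n_samples"]:
        raise ValueError(
            f"session {entry['session_id']}: manifest says {entry['n_samples']} "
            f"samples but file has {wave.size}"
        )
    return SessionRecord(
        session_id=entry["session_id"],
        waveform=wave,
        rating_arousal=entry["rating_arousal"],
        rating_valence=entry["rating_valence"],
        split=entry.get("split", "unassigned"),
        fs=entry.get("fs", FS_DEFAULT),
    )


def load_dataset(manifest_path: str | Path) -> list[SessionRecord]:
    """Load every session listed in a manifest."""
    path = Path(manifest_path)
    manifest = load_manifest(path)
    return [load_session(path.parent, e) for e in manifest]


def find_session(manifest: list[dict], session_id: str) -> dict:
    for e in manifest:
        if e["session_id"] == session_id:
            return e
    raise KeyError(f"session {session_id!r} not found in manifest")


def roundtrip_session(record: SessionRecord, directory: str | Path) -> SessionRecord:
    """Write then re-read a session; the result matches to 6 decimals."""
    entry = write_session(directory, record)
    return load_session(directory, entry)
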