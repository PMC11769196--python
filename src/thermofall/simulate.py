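"""Synthetic 8x8 thermal-scene generator with labeled activity states.

No public recordings exist for the kind of data this package analyzes, so
the simulator is the package's source of labeled streams: a single warm
body against a room-temperature background, rendered onto an 8x8 grid at
16 Hz, for six scripted activity states:

``sitting``    3x3 blob, lower-middle rows (a seated torso at mid height)
``standing``   2-wide x 5-tall column (an upright torso)
``laying``     5-wide x 2-tall strip along the bottom rows
``move_fb``    standing silhouette whose covered-pixel count swells and
               shrinks sinusoidally (~4 s period) as the subject walks
               toward and away from the sensor
``move_ud``    column height oscillating between the sitting and standing
               extents (~3 s period): repeated squatting and rising
``fall``       standing for the first third, a short (6-10 frame)
               transient in which the silhouette elongates diagonally and
               fragments, then laying for the remainder

Each frame is ambient + (body - ambient) * coverage + iid Gaussian pixel
noise, clipped to the sensor range [0, 80] C.  Fractional coverage weights
the body contribution linearly, which is how a fractionally-filled field
of view shows up on a real microbolometer grid.

Defaults (25 C ambient, 33 C body surface, 0.3 C pixel noise) put the
noiseless standing-frame sum near 1680 temperature-sum units — the order
of magnitude a 64-pixel room-temperature scene produces.  All scene
parameters are synthetic choices, not measured values.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .frames import FrameSeries, GRID_SHAPE

STATES: tuple[str, ...] = ("sitting", "standing", "laying", "move_fb", "move_ud", "fall")
NORMAL_STATES: tuple[str, ...] = ("sitting", "standing", "laying", "move_fb", "move_ud")
STATIC_STATES: tuple[str, ...] = ("sitting", "standing", "laying")


@dataclass(frozen=True)
class SceneConfig:
    """Physical parameters of the simulated scene."""

    ambient_c: float = 25.0
    body_c: float = 33.0
    pixel_noise_sd: float = 0.3
    sensor_clip: tuple[float, float] = (0.0, 80.0)
    rate_hz: float = 16.0

    def __post_init__(self) -> None:
        if not self.body_c > self.ambient_c:
            raise ValueError("body_c must exceed ambient_c")
        if self.pixel_noise_sd < 0:
            raise ValueError("pixel_noise_sd must be non-negative")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")


@dataclass(frozen=True)
class Segment:
    """One scripted activity segment."""

    state: str
    n_frames: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; choose from {STATES}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass(frozen=True)
class ActivityScript:
    """An ordered list of segments plus the seed that renders them."""

    segments: tuple[Segment, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ValueError("script needs at least one segment")


# ---------------------------------------------------------------------------
# silhouette masks

_STANDING = [(r, c) for c in (3, 4) for r in range(1, 6)]  # 2 wide x 5 tall
_SITTING = [(r, c) for r in (4, 5, 6) for c in (3, 4, 5)]  # 3x3 blob
_LAYING = [(r, c) for r in (6, 7) for c in range(1, 6)]  # 5 wide x 2 tall
# walking silhouette fill order: the standing column first, then flanking
# pixels, so coverage can range from half to 1.5x the standing area
_FB_ORDER = _STANDING + [(0, 3), (0, 4), (6, 3), (6, 4)] + [(r, 2) for r in range(1, 6)] + [
    (1, 5),
]
# fall transient pool: a 7-wide diagonal band across the grid, ordered from
# the top-left; the falling body sweeps through it with motion blur
_FALL_BAND = [(r, c) for r in range(8) for c in range(8) if abs(c - r) <= 3]


def _mask_from_pixels(pixels: Sequence[tuple[int, int]], weights=None) -> np.ndarray:
    m = np.zeros(GRID_SHAPE)
    if weights is None:
        weights = np.ones(len(pixels))
    for (r, c), w in zip(pixels, weights):
        m[r, c] = w
    return m


def _partial_fill(order: Sequence[tuple[int, int]], coverage: float) -> np.ndarray:
    """First floor(coverage) pixels at weight 1, the next at the fraction."""
    coverage = float(np.clip(coverage, 0.0, len(order)))
    full = int(coverage)
    weights = [1.0] * full
    if full < len(order) and coverage - full > 0:
        weights.append(coverage - full)
    return _mask_from_pixels(order[: len(weights)], weights)


def _mask_static(state: str) -> np.ndarray:
    return _mask_from_pixels(
        {"sitting": _SITTING, "standing": _STANDING, "laying": _LAYING}[state]
    )


def _mask_move_fb(t: float, period_s: float = 4.0) -> np.ndarray:
    base = len(_STANDING)
    coverage = base * (1.0 + 0.5 * np.sin(2.0 * np.pi * t / period_s))
    return _partial_fill(_FB_ORDER, coverage)


def _mask_move_ud(t: float, period_s: float = 3.0) -> np.ndarray:
    # column height oscillates between the sitting (3-row) and standing
    # (5-row) extents, anchored at the bottom of the standing column
    height = 4.0 + 1.0 * np.sin(2.0 * np.pi * t / period_s)
    order = [(r, c) for r in (5, 4, 3, 2, 1) for c in (3, 4)]
    return _partial_fill(order, 2.0 * height)


def _mask_fall_transient(rng: np.random.Generator) -> np.ndarray:
    """One frame of the fall transient: elongated diagonal, fragmented.

    At 16 Hz each transient frame integrates substantial body motion, so
    the silhouette smears over far more pixels than the upright column
    (28-44 covered before fragmentation, against a standing baseline of
    10 — a sprawling body with motion blur momentarily fills most of the
    low-resolution field of view).  Fragmentation then rags the coverage:
    every covered pixel keeps only 60-100% of its weight, never exceeding
    full coverage.
    """
    target = rng.uniform(28.0, 44.0)
    m = _partial_fill(_FALL_BAND, target)
    frag = rng.uniform(0.6, 1.0, size=m.shape)
    return m * frag


def _masks_for_state(
    state: str, n_frames: int, config: SceneConfig, rng: np.random.Generator
) -> np.ndarray:
    dt = 1.0 / config.rate_hz
    masks = np.empty((n_frames, *GRID_SHAPE))
    if state in STATIC_STATES:
        masks[:] = _mask_static(state)
    elif state == "move_fb":
        phase = rng.uniform(0.0, 4.0)
        for i in range(n_frames):
            masks[i] = _mask_move_fb(phase + i * dt)
    elif state == "move_ud":
        phase = rng.uniform(0.0, 3.0)
        for i in range(n_frames):
            masks[i] = _mask_move_ud(phase + i * dt)
    elif state == "fall":
        n_stand = n_frames // 3
        n_trans = int(rng.integers(6, 11))
        n_trans = min(n_trans, n_frames - n_stand)
        masks[:n_stand] = _mask_static("standing")
        for i in range(n_stand, n_stand + n_trans):
            masks[i] = _mask_fall_transient(rng)
        masks[n_stand + n_trans :] = _mask_static("laying")
    else:  # pragma: no cover - guarded by Segment validation
        raise ValueError(f"unknown state {state!r}")
    return masks


def _render(masks: np.ndarray, config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    frames = config.ambient_c + (config.body_c - config.ambient_c) * masks
    if config.pixel_noise_sd > 0:
        frames = frames + rng.normal(0.0, config.pixel_noise_sd, size=frames.shape)
    lo, hi = config.sensor_clip
    return np.clip(frames, lo, hi)


def simulate_state(
    state: str, n_frames: int, config: SceneConfig | None = None, seed=None
) -> FrameSeries:
    """A labeled single-state stream; bit-identical for a fixed seed."""
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}; choose from {STATES}")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    config = config or SceneConfig()
    rng = np.random.default_rng(seed)
    masks = _masks_for_state(state, n_frames, config, rng)
    return FrameSeries(_render(masks, config, rng), sampling_rate_hz=config.rate_hz)


def simulate_session(
    script: ActivityScript, config: SceneConfig | None = None
) -> tuple[FrameSeries, list[str]]:
    """Concatenated segments plus per-frame state labels (aligned 1:1)."""
    config = config or SceneConfig()
    rng = np.random.default_rng(script.seed)
    chunks, labels = [], []
    for seg in script.segments:
        masks = _masks_for_state(seg.state, seg.n_frames, config, rng)
        chunks.append(_render(masks, config, rng))
        labels.extend([seg.state] * seg.n_frames)
    return FrameSeries(np.concatenate(chunks), sampling_rate_hz=config.rate_hz), labels


def write_labels_csv(labels: Sequence[str], path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame_index", "state"])
        for i, s in enumerate(labels):
            w.writerow([i, s])


def read_labels_csv(path) -> list[str]:
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if rows and rows[0] and rows[0][0] == "frame_index":
        rows = rows[1:]
    return [r[1] for r in rows if r]


def noiseless_sum(state: str, config: SceneConfig | None = None) -> float:
    """Closed-form frame sum for a static state with zero noise."""
    if state not in STATIC_STATES:
        raise ValueError("closed-form sums exist only for static states")
    config = config or SceneConfig()
    mask_size = {"sitting": len(_SITTING), "standing": len(_STANDING), "laying": len(_LAYING)}
    return 64.0 * config.ambient_c + mask_size[state] * (config.body_c - config.ambient_c)
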