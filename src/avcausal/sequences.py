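"""Stochastic click-flash sequence generation.

Two event-train algorithms are provided.  The *triplet* algorithm places
events on a 60 Hz frame grid: the stimulus is divided into 3-frame (50 ms)
bins, a subset of bins is chosen uniformly at random to carry one event
each, and within a bin the event frame is uniform over the three positions
— unless the preceding bin also carries an event, in which case the frame
position is copied, which enforces a minimum 33 ms gap between events.
The *raposo* algorithm draws inter-event intervals from {60, 120} ms, with
the 60/120 mix chosen to match the nominal rate and the interval order
shuffled.

Audiovisual pairs reuse a single draw when the two modalities are meant to
be temporally coupled, and use two independent draws under temporal
conflict.  Raposo-style conflict pairs additionally shift the second
modality by 20 ms so no click ever coincides with a flash.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

#: Duration of one display frame at 60 Hz, in milliseconds.
FRAME_MS: float = 1000.0 / 60.0

#: One triplet bin = 3 frames = 50 ms.
TRIPLET_MS: float = 3 * FRAME_MS


class InvalidRateError(ValueError):
    """Requested event rate cannot be realised for the given duration."""


class RejectionFailureError(RuntimeError):
    """Rejection sampling exhausted its attempt budget."""


@dataclass(frozen=True)
class EventSequence:
    """One modality's event train.

    Parameters
    ----------
    onsets_ms : ndarray
        Strictly increasing event onset times in milliseconds, all within
        ``[0, duration_ms)``.  For triplet-algorithm sequences these are
        exact multiples of the frame duration.
    duration_ms : float
        Total presentation length in milliseconds.
    modality : str
        ``"auditory"`` or ``"visual"``.
    frame_ms : float
        Frame duration of the display grid (default 1000/60 ms).
    """

    onsets_ms: np.ndarray
    duration_ms: float
    modality: str = "auditory"
    frame_ms: float = FRAME_MS

    def __post_init__(self):
        onsets = np.asarray(self.onsets_ms, dtype=float)
        object.__setattr__(self, "onsets_ms", onsets)
        if onsets.size and not np.all(np.diff(onsets) > 0):
            raise ValueError("onsets must be strictly increasing")
        if onsets.size and (onsets[0] < 0 or onsets[-1] >= self.duration_ms):
            raise ValueError("onsets must lie in [0, duration_ms)")

    @property
    def n_events(self) -> int:
        return int(self.onsets_ms.size)

    @property
    def frames(self) -> np.ndarray:
        """Onset times as integer frame indices (rounded to the grid)."""
        return np.rint(self.onsets_ms / self.frame_ms).astype(int)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_ms / self.frame_ms))

    def as_frame_train(self) -> np.ndarray:
        """Binary indicator train over the frame grid (1 = event onset)."""
        train = np.zeros(self.n_frames, dtype=float)
        train[np.minimum(self.frames, self.n_frames - 1)] = 1.0
        return train

    def shifted(self, offset_ms: float) -> "EventSequence":
        """Shift all onsets by ``offset_ms`` (duration grows if needed)."""
        onsets = self.onsets_ms + offset_ms
        duration = max(self.duration_ms, (onsets[-1] if onsets.size else 0) + 1)
        return replace(self, onsets_ms=onsets, duration_ms=duration)


@dataclass(frozen=True)
class SequencePair:
    """Auditory + visual event trains with condition flags."""

    auditory: EventSequence
    visual: EventSequence
    nominal_rate_hz: float
    algorithm: str = "triplet"
    temporal_conflict: bool = False
    spatial_conflict: bool = False

    def __post_init__(self):
        if self.algorithm not in ("triplet", "raposo"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    def to_json_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "nominal_rate_hz": self.nominal_rate_hz,
            "temporal_conflict": self.temporal_conflict,
            "spatial_conflict": self.spatial_conflict,
            "duration_ms": self.auditory.duration_ms,
            "auditory_onsets_ms": self.auditory.onsets_ms.tolist(),
            "visual_onsets_ms": self.visual.onsets_ms.tolist(),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SequencePair":
        dur = float(d["duration_ms"])
        return cls(
            auditory=EventSequence(np.asarray(d["auditory_onsets_ms"]), dur, "auditory"),
            visual=EventSequence(np.asarray(d["visual_onsets_ms"]), dur, "visual"),
            nominal_rate_hz=float(d["nominal_rate_hz"]),
            algorithm=d["algorithm"],
            temporal_conflict=bool(d["temporal_conflict"]),
            spatial_conflict=bool(d["spatial_conflict"]),
        )


def _n_events(rate_hz: float, duration_ms: float) -> int:
    return int(round(rate_hz * duration_ms / 1000.0))


def generate_triplet_sequence(rate_hz, duration_ms, rng, modality="auditory"):
    """Generate an event train on the 60 Hz frame grid using 50 ms triplet bins.

    The number of events is ``round(rate_hz * duration_ms / 1000)``.
    Event-bearing triplets are a uniform random subset of the bins (at most
    one event per bin); within a bin the event frame is uniform over the
    three positions unless the preceding bin bears an event, in which case
    the position is copied.

    Parameters
    ----------
    rate_hz : float
        Nominal event rate (events/s), >= 0.
    duration_ms : float
        Stimulus duration; must be a multiple of 50 ms.
    rng : numpy.random.Generator
    modality : str

    Returns
    -------
    EventSequence
    """
    if rate_hz < 0:
        raise InvalidRateError("rate must be non-negative")
    n_triplets = duration_ms / TRIPLET_MS
    if abs(n_triplets - round(n_triplets)) > 1e-9:
        raise ValueError("duration_ms must be an integer number of 50 ms triplets")
    n_triplets = int(round(n_triplets))
    n_events = _n_events(rate_hz, duration_ms)
    if n_events > n_triplets:
        raise InvalidRateError(
            f"{n_events} events do not fit in {n_triplets} triplet bins"
        )
    bearing = np.sort(rng.choice(n_triplets, size=n_events, replace=False))
    # Uniform positions, then copy positions along runs of adjacent bins.
    pos = rng.integers(0, 3, size=n_events)
    if n_events:
        run_start = np.r_[True, np.diff(bearing) > 1]
        run_id = np.cumsum(run_start) - 1
        pos = pos[np.flatnonzero(run_start)][run_id]
    frames = bearing * 3 + pos
    return EventSequence(frames * FRAME_MS, float(duration_ms), modality)


def generate_raposo_sequence(rate_hz, duration_ms, rng, modality="auditory",
                             first_onset="random"):
    """Generate an event train whose inter-event intervals are 60 or 120 ms.

    The integer counts of 60 and 120 ms intervals are chosen to bring the
    mean inter-event interval closest to ``1000/rate_hz`` (so the train's
    span approximates ``(n_events - 1) * 1000/rate_hz``) and the interval
    order is uniformly shuffled.  Rates outside [1000/120, 1000/60] events/s
    use the closest achievable mix (all-120 or all-60 intervals).

    Parameters
    ----------
    first_onset : {"random", "zero"}
        Placement of the first event: uniform in the leading slack left
        after the interval chain, or at t = 0.
    """
    if rate_hz <= 0:
        raise InvalidRateError("rate must be positive")
    n_events = _n_events(rate_hz, duration_ms)
    if n_events == 0:
        return EventSequence(np.array([]), float(duration_ms), modality)
    n_int = n_events - 1
    if 60.0 * n_int > duration_ms - 1:
        raise InvalidRateError(
            f"{n_events} events need more than {duration_ms} ms at 60 ms spacing"
        )
    target_span = n_int * 1000.0 / rate_hz
    # 60*n60 + 120*(n_int-n60) closest to target_span, 0 <= n60 <= n_int
    n60 = int(round((120.0 * n_int - target_span) / 60.0))
    n60 = min(max(n60, 0), n_int)
    # shrink the chain if the rounded mix overruns the stimulus window
    while 120.0 * n_int - 60.0 * n60 > duration_ms - 1 and n60 < n_int:
        n60 += 1
    intervals = np.r_[np.full(n60, 60.0), np.full(n_int - n60, 120.0)]
    rng.shuffle(intervals)
    span = intervals.sum()
    slack = duration_ms - span
    if first_onset == "zero":
        t0 = 0.0
    elif first_onset == "random":
        t0 = rng.uniform(0.0, max(slack - 1e-6, 0.0))
    else:
        raise ValueError("first_onset must be 'random' or 'zero'")
    onsets = t0 + np.r_[0.0, np.cumsum(intervals)]
    return EventSequence(onsets, float(duration_ms), modality)


def generate_pair(temporal_conflict, spatial_conflict, rate_hz, duration_ms,
                  algorithm, rng, **kwargs) -> SequencePair:
    """Build an audiovisual sequence pair for one trial.

    Without temporal conflict both modalities share a single generated
    train.  Under temporal conflict the trains are two independent draws;
    for the raposo algorithm the visual train is additionally shifted by
    +20 ms so no click and flash ever coincide.  ``spatial_conflict`` is
    recorded as metadata only.
    """
    gen = {"triplet": generate_triplet_sequence,
           "raposo": generate_raposo_sequence}[algorithm]
    aud = gen(rate_hz, duration_ms, rng, modality="auditory", **kwargs)
    if temporal_conflict:
        vis = gen(rate_hz, duration_ms, rng, modality="visual", **kwargs)
        if algorithm == "raposo":
            vis = vis.shifted(20.0)
    else:
        vis = replace(aud, modality="visual")
    return SequencePair(aud, vis, float(rate_hz), algorithm,
                        bool(temporal_conflict), bool(spatial_conflict))


def generate_exp2_trial(rate_hz, duration_ms=2000, temporal_conflict=True,
                        rng=None, max_attempts=10_000, algorithm="triplet",
                        max_offset_filter_ms=200.0,
                        spatial_conflict=False) -> SequencePair:
    """Generate a causality-judgement trial, rejecting poorly matched pairs.

    Candidate pairs whose maximum click-flash offset exceeds
    ``max_offset_filter_ms`` (200 ms by default) are discarded and redrawn,
    which keeps the temporal correspondence of conflict trials ambiguous.
    No-conflict pairs always pass (offset 0).
    """
    from .features import max_click_flash_offset

    if rng is None:
        rng = np.random.default_rng()
    for _ in range(max_attempts):
        pair = generate_pair(temporal_conflict, spatial_conflict,
                             rate_hz, duration_ms, algorithm, rng)
        if not temporal_conflict:
            return pair
        if max_click_flash_offset(pair) <= max_offset_filter_ms:
            return pair
    raise RejectionFailureError(
        f"no pair with max offset <= {max_offset_filter_ms} ms "
        f"in {max_attempts} attempts"
    )


#: Allowed duration-jitter values: +-250 ms on a 50 ms (3 frame) grid.
JITTER_GRID_MS = np.arange(-250, 251, 50)


def jitter_duration(base_ms=2000, rng=None) -> float:
    """Draw a comparison-stimulus duration with +-250 ms jitter (50 ms grid)."""
    if rng is None:
        rng = np.random.default_rng()
    return float(base_ms + rng.choice(JITTER_GRID_MS))


# ---------------------------------------------------------------------------
# serialization

def pairs_to_json(pairs, path, seed=None):
    """Write sequence pairs to a JSON descriptor file."""
    payload = {"seed": seed, "pairs": [p.to_json_dict() for p in pairs]}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def pairs_from_json(path):
    with open(path) as fh:
        payload = json.load(fh)
    return [SequencePair.from_json_dict(d) for d in payload["pairs"]]


def sequence_to_table(pair: SequencePair):
    """Two-column (onset_ms, modality) long-format table for one pair."""
    import pandas as pd

    rows = [(t, "auditory") for t in pair.auditory.onsets_ms]
    rows += [(t, "visual") for t in pair.visual.onsets_ms]
    return pd.DataFrame(rows, columns=["onset_ms", "modality"])
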