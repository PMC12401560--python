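"""Fastball stimulus sequences and timing schedules.

A Fastball trial is a stream of mini-sequences of ``seq_len`` images:
the first ``seq_len - 1`` are novel standards and the last is one of a
small set of previously encoded oddballs. With 166 ms stimulus duration
and a 166 ms inter-stimulus interval the stream runs at a nominal 3 Hz
base rate and a nominal 0.6 Hz oddball rate. The default design uses
416 standards and 8 oddballs repeated 13 times each — 520 images and
104 oddball presentations (104 oddball cycles) per trial.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "SequenceSpec",
    "StimulusSchedule",
    "build_sequence",
    "schedule_timing",
    "validate_schedule",
]


@dataclass(frozen=True)
class SequenceSpec:
    """Parameters of a Fastball stimulus sequence.

    Attributes
    ----------
    n_standards : int
        Number of unique standard images, each shown exactly once.
    n_oddballs : int
        Number of unique oddball images.
    oddball_reps : int
        Number of presentations of each oddball image.
    seq_len : int
        Images per mini-sequence; the last one is the oddball.
    stim_dur_s, isi_s : float
        Stimulus duration and inter-stimulus interval in seconds.
    target_seq_fraction : float
        Fraction of mini-sequences flagged as fixation-target
        (fixation cross turns red) sequences.
    seed : int
        Seed for the pseudo-random ordering.
    """

    n_standards: int = 416
    n_oddballs: int = 8
    oddball_reps: int = 13
    seq_len: int = 5
    stim_dur_s: float = 0.166
    isi_s: float = 0.166
    target_seq_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_standards, self.n_oddballs, self.oddball_reps) < 1:
            raise ValueError("counts must be positive")
        if self.seq_len < 2:
            raise ValueError("seq_len must be at least 2 (standards + oddball)")
        if self.stim_dur_s <= 0 or self.isi_s <= 0:
            raise ValueError("durations must be positive")
        if not 0.0 <= self.target_seq_fraction <= 1.0:
            raise ValueError("target_seq_fraction must be in [0, 1]")
        if self.n_standards != self.n_oddballs * self.oddball_reps * (self.seq_len - 1):
            raise ValueError(
                "n_standards must equal n_oddballs * oddball_reps * (seq_len - 1) "
                f"({self.n_oddballs * self.oddball_reps * (self.seq_len - 1)}), "
                f"got {self.n_standards}"
            )

    @property
    def n_sequences(self) -> int:
        """Number of mini-sequences (= number of oddball presentations)."""
        return self.n_oddballs * self.oddball_reps

    @property
    def total_images(self) -> int:
        return self.n_standards + self.n_sequences

    @property
    def soa_s(self) -> float:
        """Stimulus-onset asynchrony: one image period in seconds."""
        return self.stim_dur_s + self.isi_s

    @property
    def base_rate_hz(self) -> float:
        """Exact image presentation rate, 1 / SOA."""
        return 1.0 / self.soa_s

    @property
    def oddball_rate_hz(self) -> float:
        """Exact oddball rate, base rate / seq_len."""
        return self.base_rate_hz / self.seq_len

    @property
    def nominal_base_rate_hz(self) -> float:
        """Base rate rounded to the nearest integer when within 2%.

        The analysis tags spectra at the nominal rate (3 Hz for the
        default 0.332 s SOA, exactly 3.012 Hz); both are recorded on the
        schedule.
        """
        nearest = round(self.base_rate_hz)
        if nearest > 0 and abs(self.base_rate_hz - nearest) / nearest <= 0.02:
            return float(nearest)
        return self.base_rate_hz

    @property
    def nominal_oddball_rate_hz(self) -> float:
        return self.nominal_base_rate_hz / self.seq_len


@dataclass
class StimulusSchedule:
    """An ordered Fastball presentation schedule.

    ``entries`` has one row per image with columns ``index`` (1-based),
    ``onset_s``, ``image_id``, ``role`` (standard/oddball) and
    ``is_target_sequence``.
    """

    entries: pd.DataFrame
    spec: SequenceSpec
    total_images: int = 0
    duration_s: float = 0.0
    base_rate_hz: float = 0.0
    oddball_rate_hz: float = 0.0
    nominal_base_rate_hz: float = 0.0
    nominal_oddball_rate_hz: float = 0.0

    def __post_init__(self) -> None:
        self.total_images = len(self.entries)

    def to_tsv(self, path) -> None:
        cols = ["index", "onset_s", "image_id", "role", "is_target_sequence"]
        self.entries[cols].to_csv(path, sep="\t", index=False)

    @staticmethod
    def from_tsv(path, spec: SequenceSpec) -> "StimulusSchedule":
        entries = pd.read_csv(path, sep="\t")
        sched = StimulusSchedule(entries=entries, spec=spec)
        return schedule_timing(sched, spec)


def _shuffle_oddballs(rng: np.random.Generator, ids: list[str], reps: int, max_tries: int) -> list[str]:
    """Order oddball presentations so no image repeats back to back.

    Random shuffles with rejection, then a greedy repair pass; raises if
    the constraint is infeasible or no valid order is found.
    """
    seq = np.array(ids * reps)
    n = len(seq)
    if reps > 1 and len(ids) == 1:
        raise ValueError("cannot avoid consecutive repeats with a single oddball image")
    for _ in range(max_tries):
        rng.shuffle(seq)
        bad = np.flatnonzero(seq[1:] == seq[:-1])
        if bad.size == 0:
            return list(seq)
        # repair: swap each offending element with a random compatible slot
        ok = True
        for i in (bad + 1):
            cand = np.flatnonzero(
                (seq != seq[i])
                & (np.r_[seq[1:], [""]] != seq[i])
                & (np.r_[[""], seq[:-1]] != seq[i])
            )
            cand = cand[cand != i]
            if cand.size == 0:
                ok = False
                break
            j = int(rng.choice(cand))
            seq[i], seq[j] = seq[j], seq[i]
        if ok and not np.any(seq[1:] == seq[:-1]):
            return list(seq)
    raise RuntimeError("could not find a non-adjacent oddball ordering")


def _pick_target_sequences(rng: np.random.Generator, n_seq: int, n_target: int, max_tries: int) -> np.ndarray:
    """Sample target-sequence positions without replacement, never two adjacent."""
    if n_target == 0:
        return np.zeros(0, dtype=int)
    if n_target > (n_seq + 1) // 2:
        raise ValueError("too many target sequences to avoid adjacency")
    for _ in range(max_tries):
        pick = np.sort(rng.choice(n_seq, size=n_target, replace=False))
        if n_target < 2 or np.min(np.diff(pick)) > 1:
            return pick
    raise RuntimeError("could not place non-adjacent target sequences")


def build_sequence(spec: SequenceSpec, max_tries: int = 1000) -> StimulusSchedule:
    """Build a pseudo-randomized Fastball schedule from ``spec``.

    Standards are drawn without replacement (each shown once); oddballs
    are ordered so that the same image never appears in consecutive
    oddball slots. ``round(target_seq_fraction * n_sequences)``
    mini-sequences are flagged as fixation-target sequences, never two
    adjacent. Identical spec + seed gives an identical schedule.
    """
    rng = np.random.default_rng(spec.seed)
    std_ids = [f"std_{i + 1:03d}" for i in range(spec.n_standards)]
    odd_ids = [f"odd_{i + 1:02d}" for i in range(spec.n_oddballs)]

    std_order = list(rng.permutation(std_ids))
    odd_order = _shuffle_oddballs(rng, odd_ids, spec.oddball_reps, max_tries)

    n_seq = spec.n_sequences
    n_target = round(spec.target_seq_fraction * n_seq)
    target_idx = set(_pick_target_sequences(rng, n_seq, n_target, max_tries).tolist())

    rows = []
    it_std = iter(std_order)
    for s in range(n_seq):
        is_target = s in target_idx
        for _ in range(spec.seq_len - 1):
            rows.append((next(it_std), "standard", is_target))
        rows.append((odd_order[s], "oddball", is_target))

    entries = pd.DataFrame(
        {
            "index": np.arange(1, len(rows) + 1),
            "onset_s": 0.0,
            "image_id": [r[0] for r in rows],
            "role": [r[1] for r in rows],
            "is_target_sequence": [r[2] for r in rows],
        }
    )
    sched = StimulusSchedule(entries=entries, spec=spec)
    sched = schedule_timing(sched, spec)
    validate_schedule(sched, spec)
    return sched


def schedule_timing(sched: StimulusSchedule, spec: SequenceSpec) -> StimulusSchedule:
    """Stamp onsets and rates onto a schedule.

    Entry k (1-based) starts at ``(k - 1) * soa``; the trial lasts
    ``total_images * soa`` seconds. Both the exact rates (1/SOA and
    1/(SOA * seq_len)) and the nominal analysis rates are recorded.
    """
    entries = sched.entries.copy()
    entries["onset_s"] = (entries["index"].to_numpy() - 1) * spec.soa_s
    out = replace(sched, entries=entries)
    out.duration_s = sched.total_images * spec.soa_s
    out.base_rate_hz = spec.base_rate_hz
    out.oddball_rate_hz = spec.oddball_rate_hz
    out.nominal_base_rate_hz = spec.nominal_base_rate_hz
    out.nominal_oddball_rate_hz = spec.nominal_oddball_rate_hz
    return out


def validate_schedule(sched: StimulusSchedule, spec: SequenceSpec) -> None:
    """Assert the structural invariants of a built schedule.

    Raises ``ValueError`` on the first violated constraint.
    """
    e = sched.entries
    if len(e) != spec.total_images:
        raise ValueError(f"expected {spec.total_images} entries, got {len(e)}")
    roles = e["role"].to_numpy()
    odd_pos = np.flatnonzero(roles == "oddball") + 1  # 1-based
    if not np.array_equal(odd_pos, np.arange(1, spec.n_sequences + 1) * spec.seq_len):
        raise ValueError("oddballs must occupy every seq_len-th position")
    odd_ids = e.loc[roles == "oddball", "image_id"].to_numpy()
    if np.any(odd_ids[1:] == odd_ids[:-1]):
        raise ValueError("consecutive oddball presentations share an image")
    counts = pd.Series(odd_ids).value_counts()
    if not (counts == spec.oddball_reps).all() or len(counts) != spec.n_oddballs:
        raise ValueError("each oddball image must appear exactly oddball_reps times")
    std_ids = e.loc[roles == "standard", "image_id"]
    if std_ids.duplicated().any():
        raise ValueError("standard images must appear exactly once")
    n_target_seq = int(e["is_target_sequence"].to_numpy().reshape(-1, spec.seq_len)[:, 0].sum())
    if n_target_seq != round(spec.target_seq_fraction * spec.n_sequences):
        raise ValueError("wrong number of fixation-target sequences")
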