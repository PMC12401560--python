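"""Synthetic Fastball EEG recordings, cohorts and behavioural tables.

The generator emulates the statistical structure the analysis assumes:
an 8-channel recording at 500 Hz containing a 3 Hz steady-state
response with harmonics, a 0.6 Hz oddball response with a harmonic
family whose per-subject amplitude differs between groups, 1/f-plus-
white noise, and occasional gross artifacts exceeding +-250 uV. Every
generated quantity is recorded in a ground-truth manifest so that
parameter-recovery tests can compare estimates against the values that
produced the data.

The paper-like amplitude scale is a documented convention (the real
study publishes no amplitudes): oddball fundamental 0.7 uV decaying
geometrically (ratio 0.85) across the harmonic family, base response
2.0 / 1.0 uV at 3 / 6 Hz, pink noise of 5 uV RMS and white noise of
3 uV RMS. These defaults give single-subject scalp-average f+ values
in the 1-4 range typical of frequency-tagged oddball recordings, with
every member of the harmonic family detectable in a group average.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fastball.preprocess import Recording
from fastball.spectral import oddball_harmonics

__all__ = [
    "GroupSpec",
    "SimulationConfig",
    "GroundTruthManifest",
    "simulate_recording",
    "simulate_cohort",
    "simulate_retest",
    "simulate_behavior",
    "BehaviorParams",
    "DEFAULT_BEHAVIOR",
]

CHANNELS: tuple[str, ...] = ("O1", "P7", "Pz", "Cz", "F3", "F4", "P8", "O2")

# Topography conventions: the base (image presentation) response is
# largest occipitally, the oddball response largest at Cz/P8.
BASE_GAIN: tuple[float, ...] = (1.00, 0.70, 0.60, 0.45, 0.35, 0.35, 0.70, 1.00)
ODDBALL_GAIN: tuple[float, ...] = (0.70, 0.75, 0.85, 1.00, 0.50, 0.50, 1.00, 0.70)


@dataclass(frozen=True)
class GroupSpec:
    """Size and oddball-amplitude distribution of one cohort group."""

    n_subjects: int
    amp_mean: float
    amp_sd: float


def _default_groups() -> dict[str, GroupSpec]:
    # Cohort sizes mirror the study (54 HOA, 33 aMCI, 20 naMCI); the
    # group means encode standardized differences d = 0.98 (aMCI vs
    # naMCI) and d = 0.64 (aMCI vs HOA) at a common subject SD of 0.30.
    sd = 0.30
    hoa = 1.0
    amci = hoa - 0.64 * sd
    namci = amci + 0.98 * sd
    return {
        "HOA": GroupSpec(54, hoa, sd),
        "aMCI": GroupSpec(33, amci, sd),
        "naMCI": GroupSpec(20, namci, sd),
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic Fastball recordings.

    ``oddball_amp_uv`` holds one amplitude per member of the oddball
    harmonic family (multiples of ``oddball_freq_hz`` up to
    ``oddball_max_hz`` that are not multiples of ``base_freq_hz``);
    a subject's amplitude factor scales the whole family.
    """

    channel_labels: tuple[str, ...] = CHANNELS
    fs_hz: float = 500.0
    base_freq_hz: float = 3.0
    oddball_freq_hz: float = 0.6
    oddball_max_hz: float = 6.6
    base_amp_uv: tuple[float, ...] = (2.0, 1.0)
    oddball_amp_uv: tuple[float, ...] | None = None
    base_gain: tuple[float, ...] = BASE_GAIN
    oddball_gain: tuple[float, ...] = ODDBALL_GAIN
    noise_pink_uv: float = 5.0
    noise_white_uv: float = 3.0
    artifact_rate_per_min: float = 0.3
    artifact_amp_uv: float = 400.0
    artifact_dur_s: float = 0.4
    duration_s: float = 176.0
    lead_in_s: float = 1.0
    n_cycles: int = 104
    groups: dict[str, GroupSpec] = field(default_factory=_default_groups)
    retest_r: float = 0.58
    session_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.oddball_amp_uv is None:
            n = len(self.oddball_freqs)
            self.oddball_amp_uv = tuple(0.7 * 0.85**i for i in range(n))
        if len(self.oddball_amp_uv) != len(self.oddball_freqs):
            raise ValueError(
                f"oddball_amp_uv needs {len(self.oddball_freqs)} entries "
                f"(one per harmonic in {self.oddball_freqs})"
            )
        if len(self.base_gain) != len(self.channel_labels) or len(self.oddball_gain) != len(self.channel_labels):
            raise ValueError("one gain per channel required")
        top = max(
            [len(self.base_amp_uv) * self.base_freq_hz]
            + [f for f in self.oddball_freqs]
        )
        if self.fs_hz <= 2 * top:
            raise ValueError(f"fs_hz must exceed twice the highest harmonic ({top} Hz)")
        if min(self.base_amp_uv) < 0 or min(self.oddball_amp_uv) < 0:
            raise ValueError("amplitudes must be non-negative")
        if not -1.0 <= self.retest_r <= 1.0:
            raise ValueError("retest_r must be in [-1, 1]")
        if self.artifact_amp_uv <= 250.0:
            raise ValueError("artifact_amp_uv must exceed the 250 uV detection threshold")
        if self.duration_s < self.lead_in_s + self.n_cycles / self.oddball_freq_hz:
            raise ValueError("duration too short for the analysis epoch plus lead-in")

    @property
    def oddball_freqs(self) -> tuple[float, ...]:
        return oddball_harmonics(self.oddball_freq_hz, self.base_freq_hz, self.oddball_max_hz)

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)


@dataclass
class GroundTruthManifest:
    """Per subject x session generative ground truth."""

    entries: list[dict] = field(default_factory=list)

    def add(self, subject_id: str, session_id: str, group: str, oddball_amp: float,
            base_amp: float, artifact_segments: list[tuple[int, int]]) -> None:
        self.entries.append(
            {
                "subject_id": subject_id,
                "session_id": session_id,
                "group": group,
                "oddball_amp": float(oddball_amp),
                "base_amp": float(base_amp),
                "artifact_segments": [list(map(int, s)) for s in artifact_segments],
            }
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.entries, fh, indent=1)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-RMS 1/f noise via frequency-domain shaping (amp ~ 1/sqrt(f))."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    coef = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))) * shape
    x = np.fft.irfft(coef, n=n)
    return x / x.std()


def simulate_recording(
    cfg: SimulationConfig,
    subject_amp: float = 1.0,
    seed: int | None = None,
    duration_s: float | None = None,
) -> tuple[Recording, dict]:
    """One synthetic recording plus its ground truth.

    The signal is the sum of base-frequency harmonics, the oddball
    harmonic family scaled by ``subject_amp``, pink and white noise,
    and square-pulse artifacts at Poisson times. Phases are drawn per
    channel and component from the seed, so the same config + seed is
    bit-identical.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    dur = cfg.duration_s if duration_s is None else duration_s
    n = round(dur * cfg.fs_hz)
    t = np.arange(n) / cfg.fs_hz
    nch = cfg.n_channels
    data = np.zeros((nch, n))

    for c in range(nch):
        for h, amp in enumerate(cfg.base_amp_uv, start=1):
            phi = rng.uniform(0, 2 * np.pi)
            data[c] += amp * cfg.base_gain[c] * np.sin(2 * np.pi * h * cfg.base_freq_hz * t + phi)
        for f, amp in zip(cfg.oddball_freqs, cfg.oddball_amp_uv):
            psi = rng.uniform(0, 2 * np.pi)
            data[c] += amp * subject_amp * cfg.oddball_gain[c] * np.sin(2 * np.pi * f * t + psi)
        if cfg.noise_pink_uv > 0:
            data[c] += cfg.noise_pink_uv * _pink_noise(rng, n, cfg.fs_hz)
        if cfg.noise_white_uv > 0:
            data[c] += cfg.noise_white_uv * rng.standard_normal(n)

    segments: list[tuple[int, int]] = []
    n_art = rng.poisson(cfg.artifact_rate_per_min * dur / 60.0)
    width = round(cfg.artifact_dur_s * cfg.fs_hz)
    for _ in range(n_art):
        s = int(rng.integers(0, max(1, n - width)))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        data[:, s : s + width] += sign * cfg.artifact_amp_uv
        segments.append((s, s + width))

    rec = Recording(data=data, fs_hz=cfg.fs_hz, channel_labels=cfg.channel_labels)
    truth = {"oddball_amp": float(subject_amp), "base_amp": 1.0, "artifact_segments": segments}
    return rec, truth


def _draw_group_amps(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for label, g in cfg.groups.items():
        amps = rng.normal(g.amp_mean, g.amp_sd, size=g.n_subjects)
        amps = np.clip(amps, 0.0, None)
        for i, a in enumerate(amps):
            rows.append({"subject_id": f"{label}_{i + 1:03d}", "group": label, "true_oddball_amp": float(a)})
    return pd.DataFrame(rows)


def simulate_cohort(
    cfg: SimulationConfig,
    seed: int | None = None,
    render: bool = True,
) -> tuple[list[tuple[str, Recording, pd.DataFrame]], pd.DataFrame, GroundTruthManifest]:
    """A single-session cohort across the configured groups.

    Subject oddball amplitudes are drawn per group from its normal
    distribution (clipped at zero). With ``render=True`` a full
    recording and event table is generated per subject; with
    ``render=False`` only the cohort table and manifest are produced —
    the mode used for large-n sampling-distribution checks.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    cohort = _draw_group_amps(cfg, rng)
    cohort["session_id"] = "1"
    manifest = GroundTruthManifest()
    recordings: list[tuple[str, Recording, pd.DataFrame]] = []
    for row in cohort.itertuples():
        if render:
            rec, truth = simulate_recording(cfg, row.true_oddball_amp, seed=int(rng.integers(2**31)))
            events = pd.DataFrame({"onset_s": [cfg.lead_in_s], "trial_id": ["trial_01"]})
            recordings.append((row.subject_id, rec, events))
            segments = truth["artifact_segments"]
        else:
            segments = []
        manifest.add(row.subject_id, "1", row.group, row.true_oddball_amp, 1.0, segments)
    return recordings, cohort, manifest


def simulate_retest(
    cfg: SimulationConfig,
    seed: int | None = None,
    render: bool = False,
) -> tuple[list[tuple[str, str, Recording, pd.DataFrame]], pd.DataFrame, GroundTruthManifest]:
    """A two-session cohort with correlated subject amplitudes.

    Session amplitudes follow a bivariate normal with correlation
    ``retest_r`` and a session-2 mean shift ``session_shift``; for
    equal session variances the population consistency ICC(C,1) equals
    ``retest_r``.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    base = _draw_group_amps(cfg, rng)
    r = cfg.retest_r
    rows = []
    manifest = GroundTruthManifest()
    recordings: list[tuple[str, str, Recording, pd.DataFrame]] = []
    for row in base.itertuples():
        g = cfg.groups[row.group]
        a1 = row.true_oddball_amp
        z = rng.standard_normal()
        a2 = g.amp_mean + cfg.session_shift + r * (a1 - g.amp_mean) + g.amp_sd * np.sqrt(max(0.0, 1 - r**2)) * z
        a2 = max(0.0, float(a2))
        for session, amp in (("1", a1), ("2", a2)):
            rows.append(
                {
                    "subject_id": row.subject_id,
                    "group": row.group,
                    "session_id": session,
                    "true_oddball_amp": float(amp),
                }
            )
            segments: list[tuple[int, int]] = []
            if render:
                rec, truth = simulate_recording(cfg, amp, seed=int(rng.integers(2**31)))
                events = pd.DataFrame({"onset_s": [cfg.lead_in_s], "trial_id": ["trial_01"]})
                recordings.append((row.subject_id, session, rec, events))
                segments = truth["artifact_segments"]
            manifest.add(row.subject_id, session, row.group, amp, 1.0, segments)
    return recordings, pd.DataFrame(rows), manifest


@dataclass(frozen=True)
class BehaviorParams:
    """Per-group behavioural generative parameters."""

    p_2afc_oddball: float = 0.93
    p_2afc_standard: float = 0.50
    rt_2afc_median_s: float = 1.2
    rt_2afc_sigma: float = 0.35
    pvt_median_s: float = 0.32
    pvt_sigma: float = 0.15
    pvt_lapse_weight: float = 0.05
    pvt_false_start_weight: float = 0.02
    p_dms48: tuple[float, float, float] = (0.98, 0.92, 0.95)  # unique, paired, abstract
    ace_memory_mean: float = 25.0
    ace_memory_sd: float = 2.0
    ace_total_mean: float = 95.0
    ace_total_sd: float = 3.0


DEFAULT_BEHAVIOR: dict[str, BehaviorParams] = {
    "HOA": BehaviorParams(),
    "naMCI": BehaviorParams(
        p_2afc_oddball=0.88,
        pvt_median_s=0.38,
        pvt_lapse_weight=0.15,
        p_dms48=(0.95, 0.85, 0.90),
        ace_memory_mean=23.5,
        ace_memory_sd=1.5,
        ace_total_mean=88.0,
        ace_total_sd=4.0,
    ),
    "aMCI": BehaviorParams(
        p_2afc_oddball=0.85,
        pvt_median_s=0.40,
        pvt_lapse_weight=0.20,
        p_dms48=(0.90, 0.75, 0.82),
        ace_memory_mean=18.5,
        ace_memory_sd=2.5,
        ace_total_mean=85.0,
        ace_total_sd=5.0,
    ),
}


def simulate_behavior(
    cohort: pd.DataFrame,
    params: dict[str, BehaviorParams] | None = None,
    seed: int = 0,
    n_pvt: int = 30,
) -> dict[str, pd.DataFrame]:
    """Behavioural response tables for a cohort.

    Returns ``{"responses": ..., "ace": ...}``: a long response table
    (2AFC, PVT and DMS-48 rows, one per trial) and an ACE-III subscale
    table. 2AFC accuracy is binomial per item class (standards at
    chance by default), response times are log-normal, PVT trials mix
    a log-normal base distribution with a lapse tail (> 500 ms) and
    occasional false starts (< 100 ms), and DMS-48 accuracy is binomial
    per 16-item subset.
    """
    params = DEFAULT_BEHAVIOR if params is None else params
    rng = np.random.default_rng(seed)
    resp_rows = []
    ace_rows = []
    subjects = cohort.drop_duplicates("subject_id")
    for row in subjects.itertuples():
        p = params[row.group]
        sid = row.subject_id
        # post-Fastball 2AFC: 8 oddballs + 8 standards vs lures
        for cls, pc in (("oddball", p.p_2afc_oddball), ("standard", p.p_2afc_standard)):
            for i in range(8):
                rt = float(np.exp(np.log(p.rt_2afc_median_s) + p.rt_2afc_sigma * rng.standard_normal()))
                resp_rows.append(
                    {
                        "subject_id": sid,
                        "task": f"fastball_2afc_{cls}",
                        "item_id": f"{cls}_{i + 1}",
                        "item_class": cls,
                        "correct": bool(rng.random() < pc),
                        "rt_s": rt,
                    }
                )
        # PVT
        for i in range(n_pvt):
            u = rng.random()
            if u < p.pvt_false_start_weight:
                rt = float(rng.uniform(0.02, 0.099))
            elif u < p.pvt_false_start_weight + p.pvt_lapse_weight:
                rt = float(rng.uniform(0.501, 1.5))
            else:
                rt = float(np.exp(np.log(p.pvt_median_s) + p.pvt_sigma * rng.standard_normal()))
            resp_rows.append(
                {
                    "subject_id": sid,
                    "task": "pvt",
                    "item_id": f"pvt_{i + 1}",
                    "item_class": "pvt",
                    "correct": True,
                    "rt_s": rt,
                }
            )
        # DMS-48: three 16-item subsets
        for cls, pc in zip(("unique", "paired", "abstract"), p.p_dms48):
            for i in range(16):
                resp_rows.append(
                    {
                        "subject_id": sid,
                        "task": "dms48",
                        "item_id": f"{cls}_{i + 1}",
                        "item_class": cls,
                        "correct": bool(rng.random() < pc),
                        "rt_s": float(np.exp(np.log(1.5) + 0.3 * rng.standard_normal())),
                    }
                )
        ace_memory = int(np.clip(round(rng.normal(p.ace_memory_mean, p.ace_memory_sd)), 0, 26))
        ace_total = int(np.clip(round(rng.normal(p.ace_total_mean, p.ace_total_sd)), 0, 100))
        ace_rows.append(
            {"subject_id": sid, "group": row.group, "ace_memory": ace_memory, "ace_total": ace_total}
        )
    return {"responses": pd.DataFrame(resp_rows), "ace": pd.DataFrame(ace_rows)}
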