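"""Raw-recording preprocessing for frequency-tagged analysis.

The fixed pipeline order is: common-average re-reference, zero-phase
lowpass, polyphase resampling to the analysis rate, integer-cycle
epoching, polynomial detrending, then amplitude-threshold artifact
suppression with half-Hanning tapers. Epochs span an exact integer
number of oddball cycles (104 cycles of 0.6 Hz by default) so the FFT
grid contains the oddball frequency and all its harmonics exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal

__all__ = [
    "Recording",
    "TrialEpoch",
    "rereference_common_average",
    "lowpass_zero_phase",
    "resample",
    "extract_epoch",
    "detrend_polynomial",
    "suppress_artifacts",
    "preprocess_recording",
]


@dataclass
class Recording:
    """Continuous multichannel EEG in microvolts.

    ``data`` is channels x samples; ``processing`` accumulates the
    stage names already applied, which lets the pipeline enforce its
    fixed stage order.
    """

    data: np.ndarray
    fs_hz: float
    channel_labels: tuple[str, ...]
    reference: str = "as-recorded"
    processing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class TrialEpoch:
    """One integer-cycle analysis window of a recording.

    ``zeroed_mask`` marks, per channel and sample, data replaced with
    zeros by artifact suppression; ``fraction_zeroed`` counts zeroed
    samples only (tapered samples are attenuated, not zeroed).
    """

    data: np.ndarray
    fs_hz: float
    onset_s: float
    n_cycles: int
    oddball_freq_hz: float
    zeroed_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    fraction_zeroed: float = 0.0
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        expected = round(self.n_cycles / self.oddball_freq_hz * self.fs_hz)
        if self.data.shape[1] != expected:
            raise ValueError(
                f"epoch must hold {expected} samples "
                f"({self.n_cycles} cycles of {self.oddball_freq_hz} Hz at {self.fs_hz} Hz), "
                f"got {self.data.shape[1]}"
            )
        if self.zeroed_mask is None:
            self.zeroed_mask = np.zeros(self.data.shape, dtype=bool)
        if not 0.0 <= self.fraction_zeroed <= 1.0:
            raise ValueError("fraction_zeroed must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def rereference_common_average(rec: Recording) -> Recording:
    """Subtract the instantaneous mean across channels from every channel."""
    if rec.n_channels < 2:
        raise ValueError("common-average reference needs at least 2 channels")
    if rec.reference != "as-recorded":
        raise ValueError(f"recording already re-referenced ({rec.reference})")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(
        rec,
        data=data,
        reference="common-average",
        processing=rec.processing + ("rereference",),
    )


def lowpass_zero_phase(rec: Recording, cutoff_hz: float = 40.0, rolloff_db_per_oct: float = 24.0) -> Recording:
    """Zero-phase Butterworth lowpass.

    The filter is applied forward and backward (``filtfilt``), so a
    24 dB/octave total rolloff uses a 2nd-order (12 dB/oct) prototype
    and the -3 dB cutoff becomes -6 dB.
    """
    if cutoff_hz >= rec.fs_hz / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    order = max(1, round(rolloff_db_per_oct / 12.0))
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rec.fs_hz, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=data, processing=rec.processing + ("lowpass",))


def resample(rec: Recording, target_hz: float = 120.0) -> Recording:
    """Polyphase rational resampling to the analysis rate.

    Requires the anti-alias lowpass to have been applied already; the
    pipeline filters at the original rate, then resamples.
    """
    if target_hz > rec.fs_hz:
        raise ValueError("upsampling is not supported")
    if "lowpass" not in rec.processing:
        raise ValueError("apply lowpass_zero_phase before resampling (anti-aliasing)")
    frac = Fraction(target_hz / rec.fs_hz).limit_denominator(1000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return replace(rec, data=data, fs_hz=float(target_hz), processing=rec.processing + ("resample",))


def extract_epoch(
    rec: Recording,
    onset_s: float,
    n_cycles: int = 104,
    oddball_freq_hz: float = 0.6,
) -> TrialEpoch:
    """Cut one integer-cycle epoch starting at ``onset_s``.

    The epoch holds ``round(n_cycles / oddball_freq_hz * fs)`` samples
    (20800 at 120 Hz for the default 104 cycles of 0.6 Hz, i.e.
    173.33 s) so that the FFT bin grid contains the oddball frequency
    and its harmonics exactly.
    """
    n = round(n_cycles / oddball_freq_hz * rec.fs_hz)
    start = round(onset_s * rec.fs_hz)
    if start < 0:
        raise ValueError("onset before start of recording")
    if start + n > rec.n_samples:
        need = (start + n) / rec.fs_hz
        raise ValueError(
            f"recording too short: {need:.2f} s required from t=0, "
            f"have {rec.duration_s:.2f} s"
        )
    return TrialEpoch(
        data=rec.data[:, start : start + n].copy(),
        fs_hz=rec.fs_hz,
        onset_s=onset_s,
        n_cycles=n_cycles,
        oddball_freq_hz=oddball_freq_hz,
        channel_labels=rec.channel_labels,
    )


def detrend_polynomial(ep: TrialEpoch, order: int = 3) -> TrialEpoch:
    """Remove a per-channel least-squares polynomial of the given order.

    Order 3 removes DC and drift slower than about one oddball cycle
    while leaving oddball-band sinusoids essentially untouched.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    if order >= ep.n_samples:
        raise ValueError("polynomial order must be below the sample count")
    # x in [-1, 1] for conditioning
    x = np.linspace(-1.0, 1.0, ep.n_samples)
    V = np.polynomial.polynomial.polyvander(x, order)
    coef, *_ = np.linalg.lstsq(V, ep.data.T, rcond=None)
    data = ep.data - (V @ coef).T
    return replace(ep, data=data)


def _taper_envelope(n: int, runs: list[tuple[int, int]], taper_points: int) -> np.ndarray:
    """Envelope that is 0 inside runs and ramps 0 -> 1 over taper_points.

    Half-Hanning ramps flank every run; overlapping ramps combine by
    pointwise minimum so merged artifacts keep a monotone envelope.
    """
    env = np.ones(n)
    d = np.arange(1, taper_points + 1)
    ramp = 0.5 * (1.0 - np.cos(np.pi * d / taper_points))  # 0-ish near run, 1 far away
    for s, e in runs:  # run occupies [s, e)
        env[s:e] = 0.0
        left = np.arange(s - 1, s - 1 - taper_points, -1)
        keep = left >= 0
        env[left[keep]] = np.minimum(env[left[keep]], ramp[keep])
        right = np.arange(e, e + taper_points)
        keep = right < n
        env[right[keep]] = np.minimum(env[right[keep]], ramp[keep])
    return env


def _find_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal contiguous True stretches of a boolean vector as [s, e)."""
    if not mask.any():
        return []
    padded = np.r_[False, mask, False]
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def suppress_artifacts(ep: TrialEpoch, threshold_uv: float = 250.0, taper_points: int = 670) -> TrialEpoch:
    """Zero gross artifacts and taper the flanking data.

    Per channel, every maximal run of samples with ``|v| > threshold``
    is replaced with zeros; clean data on each side of a run is scaled
    by a half-Hanning ramp descending to zero over ``taper_points``
    samples, so the remaining signal has no discontinuity. Runs closer
    than a taper length merge their ramps by pointwise minimum.
    ``fraction_zeroed`` counts zeroed samples only.
    """
    if taper_points < 1:
        raise ValueError("taper_points must be >= 1")
    data = ep.data.copy()
    mask = np.abs(data) > threshold_uv
    if mask.any():
        for c in range(data.shape[0]):
            runs = _find_runs(mask[c])
            if runs:
                data[c] *= _taper_envelope(data.shape[1], runs, taper_points)
    new_mask = ep.zeroed_mask | mask
    return replace(
        ep,
        data=data,
        zeroed_mask=new_mask,
        fraction_zeroed=float(new_mask.mean()),
    )


def preprocess_recording(
    rec: Recording,
    onsets_s,
    *,
    cutoff_hz: float = 40.0,
    rolloff_db_per_oct: float = 24.0,
    target_hz: float = 120.0,
    n_cycles: int = 104,
    oddball_freq_hz: float = 0.6,
    detrend_order: int = 3,
    artifact_threshold_uv: float = 250.0,
    taper_points: int = 670,
) -> list[TrialEpoch]:
    """Run the fixed preprocessing chain and return one epoch per onset.

    Order: re-reference -> lowpass -> resample -> epoch -> detrend ->
    artifact suppression. Detrending precedes artifact zeroing so that
    inserted zeros cannot bias the polynomial fit.
    """
    rec = rereference_common_average(rec)
    rec = lowpass_zero_phase(rec, cutoff_hz, rolloff_db_per_oct)
    rec = resample(rec, target_hz)
    epochs = []
    for onset in np.atleast_1d(onsets_s):
        ep = extract_epoch(rec, float(onset), n_cycles, oddball_freq_hz)
        ep = detrend_polynomial(ep, detrend_order)
        ep = suppress_artifacts(ep, artifact_threshold_uv, taper_points)
        epochs.append(ep)
    return epochs
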