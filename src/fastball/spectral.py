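"""Amplitude spectra, neighbour-bin SNR and the F / f+ metrics.

The frequency-tagged response is quantified as signal-to-noise ratio:
the amplitude in a bin divided by the mean amplitude of surrounding
bins within +-0.10 Hz, excluding the first neighbouring bin on each
side (which may carry leaked signal). ``F`` is the SNR at the base
presentation frequency (3 Hz, visuo-attentional engagement); ``f+`` is
the mean SNR over the oddball frequency and its significant harmonics,
excluding multiples of the base frequency — the neural
recognition-memory metric.

Harmonics enter f+ by a group-level criterion: Z-scores of the
grand-average global (all-electrode) spectrum at each candidate
harmonic against its +-0.10 Hz neighbourhood, with candidates included
while Z > 1.96.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fastball.preprocess import TrialEpoch

__all__ = [
    "AmplitudeSpectrum",
    "SNRSpectrum",
    "HarmonicSelection",
    "FastballMetrics",
    "DEFAULT_HARMONICS",
    "amplitude_spectrum",
    "snr_spectrum",
    "harmonic_group_z",
    "compute_fastball_metrics",
    "oddball_harmonics",
    "metrics_table",
]

#: Oddball harmonic set reported for healthy older adults: multiples of
#: 0.6 Hz up to 6.6 Hz, excluding the base-frequency multiples 3 and 6 Hz.
DEFAULT_HARMONICS: tuple[float, ...] = (0.6, 1.2, 1.8, 2.4, 3.6, 4.2, 4.8, 5.4, 6.6)


def oddball_harmonics(
    oddball_freq_hz: float = 0.6,
    base_freq_hz: float = 3.0,
    max_hz: float = 6.6,
) -> tuple[float, ...]:
    """Multiples of the oddball frequency up to ``max_hz``, excluding
    integer multiples of the base frequency."""
    out = []
    k = 1
    while k * oddball_freq_hz <= max_hz + 1e-9:
        f = k * oddball_freq_hz
        ratio = f / base_freq_hz
        if abs(ratio - round(ratio)) > 1e-9:
            out.append(round(f, 10))
        k += 1
    return tuple(out)


@dataclass
class AmplitudeSpectrum:
    """Single-sided amplitude spectrum (channels x bins, microvolts).

    Normalisation is 2|X_k|/N for k > 0, so a unit-amplitude
    bin-aligned sinusoid has amplitude 1.0 in its bin.
    """

    freqs_hz: np.ndarray
    amp_uv: np.ndarray
    df_hz: float
    channel_labels: tuple[str, ...] = ()

    def global_average(self) -> np.ndarray:
        """Mean amplitude across channels (the 'global' spectrum)."""
        return self.amp_uv.mean(axis=0)


@dataclass
class SNRSpectrum:
    """Neighbour-bin SNR (channels x bins, unitless).

    Bins lacking a full +-half_width neighbourhood are NaN
    (unavailable).
    """

    freqs_hz: np.ndarray
    snr: np.ndarray
    df_hz: float
    half_width_hz: float = 0.10
    n_adjacent_excluded: int = 1
    channel_labels: tuple[str, ...] = ()


@dataclass
class HarmonicSelection:
    """Data-driven choice of oddball harmonics entering f+."""

    candidates: tuple[tuple[float, float], ...]  # (freq_hz, group_Z)
    z_crit: float
    included: tuple[float, ...]
    excluded_base_multiples: tuple[float, ...]

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.candidates, columns=["freq_hz", "group_z"])
        df["included"] = [f in self.included for f in df["freq_hz"]]
        return df


@dataclass
class FastballMetrics:
    """Per-subject Fastball summary metrics.

    ``F_snr`` — SNR at the base frequency per electrode;
    ``f_plus`` — mean SNR over the included harmonics per electrode;
    scalp average and maximal electrode summarise across electrodes.
    """

    subject_id: str
    session_id: str
    channel_labels: tuple[str, ...]
    F_snr: np.ndarray
    f_plus: np.ndarray
    F_snr_scalp_avg: float = field(init=False)
    f_plus_scalp_avg: float = field(init=False)
    f_plus_max: float = field(init=False)
    max_electrode: str = field(init=False)

    def __post_init__(self) -> None:
        self.F_snr = np.asarray(self.F_snr, dtype=float)
        self.f_plus = np.asarray(self.f_plus, dtype=float)
        self.F_snr_scalp_avg = float(self.F_snr.mean())
        self.f_plus_scalp_avg = float(self.f_plus.mean())
        imax = int(np.argmax(self.f_plus))  # ties -> first in channel order
        self.f_plus_max = float(self.f_plus[imax])
        self.max_electrode = self.channel_labels[imax]


def amplitude_spectrum(ep: TrialEpoch) -> AmplitudeSpectrum:
    """FFT amplitude spectrum of an integer-cycle epoch."""
    n = ep.n_samples
    if n == 0:
        raise ValueError("empty epoch")
    X = np.fft.rfft(ep.data, axis=1)
    amp = np.abs(X) / n
    amp[:, 1:] *= 2.0
    if n % 2 == 0:
        amp[:, -1] /= 2.0  # Nyquist bin is not doubled
    freqs = np.fft.rfftfreq(n, d=1.0 / ep.fs_hz)
    return AmplitudeSpectrum(
        freqs_hz=freqs,
        amp_uv=amp,
        df_hz=ep.fs_hz / n,
        channel_labels=ep.channel_labels,
    )


def _neighbourhood_offsets(df_hz: float, half_width_hz: float, n_excluded: int) -> np.ndarray:
    """Signed bin offsets forming the SNR baseline neighbourhood."""
    n_half = int(np.floor(half_width_hz / df_hz + 1e-9))
    if n_half <= n_excluded:
        raise ValueError("neighbourhood empty: widen half_width_hz or reduce exclusions")
    offs = np.arange(n_excluded + 1, n_half + 1)
    return np.r_[-offs[::-1], offs]


def _neighbour_mean_sd(amp: np.ndarray, offsets: np.ndarray):
    """Mean and sd over neighbourhood bins for every bin, NaN at edges.

    ``amp`` is (..., bins); computed by stacking shifted copies, which
    keeps the arithmetic identical to an explicit per-bin loop.
    """
    nb = amp.shape[-1]
    reach = int(np.max(np.abs(offsets)))
    stack = np.full((len(offsets),) + amp.shape, np.nan)
    for i, o in enumerate(offsets):
        if o > 0:
            stack[i, ..., : nb - o] = amp[..., o:]
        else:
            stack[i, ..., -o:] = amp[..., :o]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    mean[..., :reach] = np.nan
    mean[..., nb - reach :] = np.nan
    sd[..., :reach] = np.nan
    sd[..., nb - reach :] = np.nan
    return mean, sd


def snr_spectrum(
    spec: AmplitudeSpectrum,
    half_width_hz: float = 0.10,
    n_adjacent_excluded: int = 1,
) -> SNRSpectrum:
    """Divide every bin by the mean of its +-half_width neighbourhood.

    The ``n_adjacent_excluded`` nearest bins on each side are left out
    of the baseline so leaked signal does not inflate it. With the
    default 104-cycle epoch (df ~ 0.00577 Hz) the neighbourhood is 17
    bins per side minus 1 excluded = 32 bins.
    """
    offsets = _neighbourhood_offsets(spec.df_hz, half_width_hz, n_adjacent_excluded)
    mean, _ = _neighbour_mean_sd(spec.amp_uv, offsets)
    with np.errstate(invalid="ignore", divide="ignore"):
        snr = spec.amp_uv / mean
    return SNRSpectrum(
        freqs_hz=spec.freqs_hz,
        snr=snr,
        df_hz=spec.df_hz,
        half_width_hz=half_width_hz,
        n_adjacent_excluded=n_adjacent_excluded,
        channel_labels=spec.channel_labels,
    )


def _nearest_bin(freqs: np.ndarray, f: float, df_hz: float) -> int:
    k = int(np.argmin(np.abs(freqs - f)))
    if abs(freqs[k] - f) >= df_hz / 2:
        raise ValueError(f"frequency {f} Hz is not on the bin grid (df = {df_hz:.6f} Hz)")
    return k


def harmonic_group_z(
    subject_spectra: list[AmplitudeSpectrum],
    base_freq_hz: float = 3.0,
    oddball_freq_hz: float = 0.6,
    max_candidate_hz: float = 20.0,
    z_crit: float = 1.96,
    half_width_hz: float = 0.10,
    n_adjacent_excluded: int = 1,
    use_snr: bool = False,
    stop: str = "first_gap",
) -> HarmonicSelection:
    """Select the oddball harmonics entering f+ from group-level Z-scores.

    Candidates are multiples of the oddball frequency up to
    ``max_candidate_hz`` that are not multiples of the base frequency.
    For each candidate, Z = (value_at_bin - mean(neighbourhood)) /
    sd(neighbourhood) on the grand average of the subjects'
    global-average (all-electrode) amplitude spectra; ``use_snr=True``
    scores the SNR-transformed grand average instead.

    ``stop`` controls the stopping rule:

    * ``"first_gap"`` (default) — include candidates from the lowest
      upward while Z > z_crit, stopping at the first non-significant
      one. Robust to isolated chance exceedances among high-frequency
      noise candidates.
    * ``"highest"`` — include every candidate up to the highest one
      with Z > z_crit, regardless of gaps.

    One selection is shared by all subjects (group-level, not
    per-subject).
    """
    if stop not in ("first_gap", "highest"):
        raise ValueError("stop must be 'first_gap' or 'highest'")
    if not subject_spectra:
        raise ValueError("no subject spectra provided")
    ref = subject_spectra[0]
    grand = np.mean([s.global_average() for s in subject_spectra], axis=0)
    if use_snr:
        grand_spec = AmplitudeSpectrum(ref.freqs_hz, grand[None, :], ref.df_hz)
        grand = snr_spectrum(grand_spec, half_width_hz, n_adjacent_excluded).snr[0]
    offsets = _neighbourhood_offsets(ref.df_hz, half_width_hz, n_adjacent_excluded)
    mean, sd = _neighbour_mean_sd(grand, offsets)

    cands = oddball_harmonics(oddball_freq_hz, base_freq_hz, max_candidate_hz)
    excluded = tuple(
        round(k * oddball_freq_hz, 10)
        for k in range(1, int(max_candidate_hz / oddball_freq_hz) + 1)
        if round(k * oddball_freq_hz, 10) not in cands
    )
    scored: list[tuple[float, float]] = []
    for f in cands:
        k = _nearest_bin(ref.freqs_hz, f, ref.df_hz)
        if not np.isfinite(sd[k]) or sd[k] == 0:
            raise ValueError(f"Z unavailable at {f} Hz (degenerate neighbourhood)")
        scored.append((f, float((grand[k] - mean[k]) / sd[k])))

    sig = [f for f, z in scored if z > z_crit]
    if not sig:
        included: tuple[float, ...] = ()
    elif stop == "highest":
        top = max(sig)
        included = tuple(f for f, _ in scored if f <= top)
    else:
        included = []
        for f, z in scored:
            if z > z_crit:
                included.append(f)
            else:
                break
        included = tuple(included)
    return HarmonicSelection(
        candidates=tuple(scored),
        z_crit=z_crit,
        included=included,
        excluded_base_multiples=excluded,
    )


def compute_fastball_metrics(
    snr: SNRSpectrum,
    sel: HarmonicSelection | None = None,
    base_freq_hz: float = 3.0,
    subject_id: str = "",
    session_id: str = "",
) -> FastballMetrics:
    """F and f+ per electrode, scalp average, and maximal electrode.

    If the harmonic selection is empty (no significant harmonics), f+
    falls back to the nominal default harmonic list with a warning.
    """
    if sel is None or not sel.included:
        if sel is not None:
            warnings.warn(
                "no significant harmonics; using the nominal default list "
                f"{DEFAULT_HARMONICS}",
                stacklevel=2,
            )
        harmonics = DEFAULT_HARMONICS
    else:
        harmonics = sel.included

    missing = []
    idx = []
    for f in harmonics:
        k = _nearest_bin(snr.freqs_hz, f, snr.df_hz)
        if not np.all(np.isfinite(snr.snr[:, k])):
            missing.append(f)
        idx.append(k)
    if missing:
        raise ValueError(f"SNR unavailable at included frequencies: {missing}")
    kF = _nearest_bin(snr.freqs_hz, base_freq_hz, snr.df_hz)
    if not np.all(np.isfinite(snr.snr[:, kF])):
        raise ValueError(f"SNR unavailable at the base frequency {base_freq_hz} Hz")

    labels = snr.channel_labels or tuple(f"ch{i}" for i in range(snr.snr.shape[0]))
    return FastballMetrics(
        subject_id=subject_id,
        session_id=session_id,
        channel_labels=labels,
        F_snr=snr.snr[:, kF],
        f_plus=snr.snr[:, idx].mean(axis=1),
    )


def metrics_table(metrics: list[FastballMetrics], group_labels: dict[str, str] | None = None) -> pd.DataFrame:
    """Stack per-subject metrics into a long table.

    One row per subject x session x electrode, plus the scalp-average
    and maximal-electrode summary columns repeated on each row — the
    layout expected by the group-statistics layer.
    """
    rows = []
    for m in metrics:
        for e, label in enumerate(m.channel_labels):
            rows.append(
                {
                    "subject_id": m.subject_id,
                    "session_id": m.session_id,
                    "group": (group_labels or {}).get(m.subject_id, ""),
                    "electrode": label,
                    "F_snr": m.F_snr[e],
                    "f_plus": m.f_plus[e],
                    "F_snr_scalp_avg": m.F_snr_scalp_avg,
                    "f_plus_scalp_avg": m.f_plus_scalp_avg,
                    "f_plus_max": m.f_plus_max,
                    "max_electrode": m.max_electrode,
                }
            )
    return pd.DataFrame(rows)
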