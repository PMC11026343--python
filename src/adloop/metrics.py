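"""Spectral, synchrony, staging and spatiotemporal summary statistics.

Spectra are Welch-averaged periodograms at <= 0.5 Hz resolution.  Functional
connectivity is the phase-locking value (PLV): signals are zero-phase
band-pass filtered (order-4 Butterworth, applied forward and backward), the
instantaneous phase is taken from the analytic signal, and the modulus of
the time-averaged unit phasor of the phase difference is reported, with 10%
of samples trimmed at each edge to suppress filter transients.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt, welch

from .neural import NeuralRecording

__all__ = [
    "DELTA", "THETA", "ALPHA", "TOTAL_BAND",
    "SpectralSummary", "FCMatrix", "TimeToPeak",
    "power_spectrum", "spectral_peak", "relative_band_power",
    "spectral_summary", "plv_matrix", "mean_fc",
    "dominant_braak_sequence", "time_to_peak",
]

DELTA = (2.0, 4.0)
THETA = (4.0, 8.0)
ALPHA = (8.0, 12.0)
#: Denominator range for relative powers and peak search.
TOTAL_BAND = (2.0, 40.0)

#: Stage means below this floor (M) do not contribute to Braak ranking.
BRAAK_ACTIVITY_FLOOR = 1e-4

_CANONICAL_STAGES = ("I", "II", "III", "IV", "V")


@dataclass
class SpectralSummary:
    """Per-region peak frequency and absolute/relative band powers."""

    peak_hz: np.ndarray
    abs_power: dict          # band name -> (n,) array
    rel_power: dict          # band name -> (n,) array


@dataclass
class FCMatrix:
    """Pairwise phase-locking values in one frequency band."""

    values: np.ndarray
    band: tuple[float, float]
    window_s: float

    @property
    def n(self) -> int:
        return self.values.shape[0]


class TimeToPeak(NamedTuple):
    year: float
    interior: bool  # False when the peak sits on the series boundary


def _as_signal(recording, region=None, fs=None):
    if isinstance(recording, NeuralRecording):
        x = recording.data if region is None else recording.data[region]
        return np.asarray(x, float), recording.fs
    if fs is None:
        raise ValueError("fs required for raw arrays")
    x = np.asarray(recording, float)
    return (x if region is None else x[region]), float(fs)


def power_spectrum(recording, region=None, fs=None):
    """Welch PSD with ~0.5 Hz resolution, Hann taper, 50% overlap.

    Returns ``(freqs, psd)``; for multi-region input the PSD has shape
    (n_regions, n_freqs).
    """
    x, fs = _as_signal(recording, region, fs)
    nper = int(round(2.0 * fs))  # 2 s segments -> 0.5 Hz bins
    if nper > x.shape[-1]:
        raise ValueError("window longer than signal")
    return welch(x, fs=fs, nperseg=nper, noverlap=nper // 2,
                 window="hann", axis=-1)


def spectral_peak(recording, region=None, search_band=TOTAL_BAND, fs=None):
    """Frequency (Hz) of the PSD maximum within ``search_band``."""
    f, p = power_spectrum(recording, region, fs)
    m = (f >= search_band[0]) & (f <= search_band[1])
    if p.ndim == 1:
        return float(f[m][np.argmax(p[m])])
    return f[m][np.argmax(p[:, m], axis=-1)]


def band_power(recording, region=None, band=ALPHA, fs=None):
    """Band-integrated PSD (trapezoidal)."""
    f, p = power_spectrum(recording, region, fs)
    m = (f >= band[0]) & (f <= band[1])
    return np.trapezoid(p[..., m], f[m], axis=-1)


def relative_band_power(recording, region=None, band=ALPHA, fs=None,
                        total_band=TOTAL_BAND):
    """Band power as a fraction of the 2-40 Hz total; in [0, 1]."""
    num = band_power(recording, region, band, fs)
    den = band_power(recording, region, total_band, fs)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return float(out) if np.ndim(out) == 0 else out


def spectral_summary(recording, bands=None, fs=None) -> SpectralSummary:
    bands = bands or {"delta": DELTA, "theta": THETA, "alpha": ALPHA}
    return SpectralSummary(
        peak_hz=np.atleast_1d(spectral_peak(recording, fs=fs)),
        abs_power={k: np.atleast_1d(band_power(recording, band=b, fs=fs))
                   for k, b in bands.items()},
        rel_power={k: np.atleast_1d(
            relative_band_power(recording, band=b, fs=fs))
            for k, b in bands.items()},
    )


def plv_matrix(recording, band=ALPHA, fs=None, trim_frac=0.1) -> FCMatrix:
    """Phase-locking value matrix.

    ``PLV_jk = | mean_t exp(i (phi_j(t) - phi_k(t))) |`` with phases from
    the analytic signal of the band-passed traces.  Symmetric, unit
    diagonal, entries in [0, 1].
    """
    x, fs = _as_signal(recording, None, fs)
    x = np.atleast_2d(x)
    if x.shape[0] < 2:
        raise ValueError("PLV needs at least two regions")
    nyq = fs / 2.0
    if band[1] >= nyq or band[0] <= 0:
        raise ValueError(f"band {band} outside (0, {nyq}) Hz")
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    filt = sosfiltfilt(sos, x, axis=-1)
    phase = np.angle(hilbert(filt, axis=-1))
    t = phase.shape[-1]
    lo, hi = int(trim_frac * t), t - int(trim_frac * t)
    phasor = np.exp(1j * phase[:, lo:hi])
    # mean over time of exp(i (phi_j - phi_k)), all pairs at once
    m = phasor @ phasor.conj().T / phasor.shape[-1]
    vals = np.abs(m)
    vals = 0.5 * (vals + vals.T)
    np.fill_diagonal(vals, 1.0)
    return FCMatrix(values=np.clip(vals, 0.0, 1.0), band=tuple(band),
                    window_s=(hi - lo) / fs)


def mean_fc(fc, region_subset=None) -> float:
    """Mean of the upper-triangle PLV entries, optionally restricted to a
    region subset."""
    vals = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, float)
    if region_subset is not None:
        idx = np.asarray(region_subset, int)
        vals = vals[np.ix_(idx, idx)]
    iu = np.triu_indices(vals.shape[0], k=1)
    if iu[0].size == 0:
        raise ValueError("subset too small for any region pair")
    return float(vals[iu].mean())


def dominant_braak_sequence(tau_trajectory: np.ndarray,
                            stage_map: Sequence[str]) -> tuple[str, ...]:
    """Modal ordering of Braak stage groups by mean toxic-tau load.

    At each trajectory step the mean toxic tau per stage group (I-V) is
    ranked in descending order (ties broken by canonical stage order); the
    most frequent ranking over the steps where at least one stage mean
    exceeds the activity floor is returned.
    """
    tau = np.asarray(tau_trajectory, float)
    stage_map = list(stage_map)
    if tau.ndim != 2 or tau.shape[1] != len(stage_map):
        raise ValueError("trajectory/stage_map shape mismatch")
    groups = {}
    for s in _CANONICAL_STAGES:
        idx = [i for i, lab in enumerate(stage_map) if lab == s]
        if not idx:
            raise ValueError(f"empty Braak stage group {s}")
        groups[s] = np.asarray(idx)
    means = np.column_stack([tau[:, groups[s]].mean(axis=1)
                             for s in _CANONICAL_STAGES])
    active = means.max(axis=1) > BRAAK_ACTIVITY_FLOOR
    if not np.any(active):
        raise ValueError("no trajectory step above the activity floor")
    seqs = []
    for row in means[active]:
        # descending concentration; canonical stage order breaks ties
        order = sorted(range(5), key=lambda k: (-row[k], k))
        seqs.append(tuple(_CANONICAL_STAGES[k] for k in order))
    return Counter(seqs).most_common(1)[0][0]


def time_to_peak(series_by_year: np.ndarray, group=None,
                 years: np.ndarray | None = None) -> TimeToPeak:
    """Year of the (3-point smoothed) maximum of a yearly group average.

    ``series_by_year`` is (Y,) or (Y, n); ``group`` selects the region
    columns averaged.  A peak on the first or last year is flagged as
    non-interior (e.g. a monotone series).
    """
    x = np.asarray(series_by_year, float)
    if x.ndim == 2:
        x = x.mean(axis=1) if group is None \
            else x[:, np.asarray(group, int)].mean(axis=1)
    if years is None:
        years = np.arange(x.size)
    sm = np.convolve(x, np.ones(3) / 3.0, mode="same")
    # edges average only the available neighbours
    sm[0] = x[:2].mean()
    sm[-1] = x[-2:].mean()
    k = int(np.argmax(sm))
    return TimeToPeak(year=float(years[k]),
                      interior=bool(0 < k < x.size - 1))
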