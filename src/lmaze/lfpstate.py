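"""LFP spectral state analysis.

Spectrograms and Welch PSDs, robust aperiodic (1/f) fits and their residuals,
cross-frequency power correlations, theta/LIA state classification from the
normalized log theta:delta power ratio, and cycle-by-cycle theta segmentation
with ascending/descending asymmetry metrics.

Phase convention follows the hippocampal pyramidal layer: descending runs
from an LFP peak to the following trough, ascending from the trough to the
next peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import signal

from .core import BandDefinitions, LFPSignal

THETA_CYCLE_COLUMNS = [
    "t_peak", "t_trough", "t_end", "dur_desc", "dur_asc", "asymmetry",
]


@dataclass
class Spectrogram:
    freqs: np.ndarray       # Hz
    t: np.ndarray           # bin centers, s
    power: np.ndarray       # (n_freqs, n_bins), density
    bin_length: float

    @property
    def n_bins(self) -> int:
        return self.power.shape[1]


@dataclass
class PSDCurve:
    freqs: np.ndarray
    power: np.ndarray

    def band_power(self, band: tuple[float, float]) -> float:
        """Mean power across the frequencies of the band."""
        sel = (self.freqs >= band[0]) & (self.freqs <= band[1])
        if not sel.any():
            raise ValueError(f"band {band} outside PSD support")
        return float(self.power[sel].mean())


@dataclass
class StateSeries:
    """Per-bin theta/LIA labels from the normalized log theta:delta ratio."""

    t: np.ndarray             # bin centers
    ratio: np.ndarray         # normalized log(theta/delta)
    is_theta: np.ndarray      # bool per bin
    bin_length: float
    threshold: float

    def theta_at(self, times: np.ndarray) -> np.ndarray:
        """Theta-state flag at arbitrary times (nearest bin)."""
        idx = np.clip(
            np.round((np.asarray(times) - self.t[0]) / self.bin_length).astype(int),
            0, len(self.t) - 1,
        )
        return self.is_theta[idx]

    def theta_intervals(self) -> np.ndarray:
        """(n, 2) start/end times of contiguous theta-labeled bins."""
        if not self.is_theta.any():
            return np.empty((0, 2))
        m = self.is_theta.astype(int)
        edges = np.flatnonzero(np.diff(m))
        starts = list(edges[m[edges] == 0] + 1)
        ends = list(edges[m[edges] == 1] + 1)
        if self.is_theta[0]:
            starts.insert(0, 0)
        if self.is_theta[-1]:
            ends.append(len(m))
        half = self.bin_length / 2.0
        return np.array(
            [[self.t[s] - half, self.t[e - 1] + half] for s, e in zip(starts, ends)]
        )


def compute_spectrogram(
    x: np.ndarray, fs: float, bin_length: float = 1.0
) -> Spectrogram:
    """Non-overlapping spectrogram with the stated bin length (density
    scaling), the base representation for PSD and state analyses."""
    nper = int(round(bin_length * fs))
    if len(x) < 2 * nper:
        raise ValueError("segment must be at least 2 spectrogram bins long")
    freqs, t, sxx = signal.spectrogram(
        np.asarray(x, dtype=float), fs=fs, nperseg=nper, noverlap=0,
        window="hann", scaling="density", detrend="constant",
    )
    return Spectrogram(freqs=freqs, t=t, power=sxx, bin_length=bin_length)


def compute_psd(
    source: Spectrogram | np.ndarray,
    fs: float | None = None,
    bins: np.ndarray | None = None,
    bin_length: float = 1.0,
) -> PSDCurve:
    """Welch PSD: the mean of the spectrogram's periodograms, optionally
    restricted to a bin selection (for event-aligned comparisons)."""
    if isinstance(source, Spectrogram):
        spec = source
    else:
        if fs is None:
            raise ValueError("fs is required when passing a raw signal")
        spec = compute_spectrogram(source, fs, bin_length)
    pw = spec.power if bins is None else spec.power[:, bins]
    if pw.shape[1] == 0:
        raise ValueError("no spectrogram bins selected")
    return PSDCurve(freqs=spec.freqs, power=pw.mean(axis=1))


def fit_aperiodic_residual(
    psd: PSDCurve, fit_band: tuple[float, float] = (80.0, 400.0)
) -> tuple[PSDCurve, dict]:
    """Robust log-log line fit of the aperiodic component over ``fit_band``;
    the residual (observed minus fitted power, linear units) isolates
    oscillatory power such as the ripple band."""
    sel = (psd.freqs >= fit_band[0]) & (psd.freqs <= fit_band[1]) & (psd.freqs > 0)
    if sel.sum() < 10:
        raise ValueError(f"fewer than 10 PSD points in fit band {fit_band}")
    f = psd.freqs[sel]
    p = psd.power[sel]
    if np.any(p <= 0):
        raise ValueError("non-positive PSD values in fit band")
    X = sm.add_constant(np.log10(f))
    rlm = sm.RLM(np.log10(p), X, M=sm.robust.norms.HuberT()).fit()
    fitted = 10.0 ** rlm.predict(X)
    residual = PSDCurve(freqs=f, power=p - fitted)
    info = {"intercept": float(rlm.params[0]), "slope": float(rlm.params[1])}
    return residual, info


def crossfreq_correlation(spec: Spectrogram, log: bool = True) -> pd.DataFrame:
    """Frequency x frequency correlation of (log) power across time bins; a
    high-correlation block spanning 150-250 Hz marks genuine SWR activity."""
    if spec.n_bins < 30:
        raise ValueError("need at least 30 time bins for cross-frequency correlation")
    pw = spec.power
    data = np.log10(np.maximum(pw, np.finfo(float).tiny)) if log else pw
    sd = data.std(axis=1)
    flat = sd <= 1e-12 * (1.0 + np.abs(data.mean(axis=1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(data)
    mat[flat, :] = np.nan
    mat[:, flat] = np.nan
    np.fill_diagonal(mat, np.where(flat, np.nan, 1.0))
    return pd.DataFrame(mat, index=spec.freqs, columns=spec.freqs)


def classify_state(
    x: np.ndarray | LFPSignal,
    fs: float | None = None,
    bands: BandDefinitions | None = None,
    threshold: float = 0.5,
    bin_length: float = 1.0,
    channel: int = 0,
) -> StateSeries:
    """Theta vs LIA per time bin.

    The per-bin log(theta power / delta power) is z-normalized over the
    session; bins at or above ``threshold`` are theta.  The ratio is
    invariant to overall LFP gain.
    """
    if isinstance(x, LFPSignal):
        fs = x.fs
        x = x.channel(channel)
    if fs is None:
        raise ValueError("fs is required when passing a raw signal")
    bands = bands or BandDefinitions()
    spec = compute_spectrogram(x, fs, bin_length)
    th_sel = (spec.freqs >= bands.theta[0]) & (spec.freqs <= bands.theta[1])
    de_sel = (spec.freqs >= bands.delta[0]) & (spec.freqs <= bands.delta[1])
    tiny = np.finfo(float).tiny
    ratio = np.log(np.maximum(spec.power[th_sel].mean(axis=0), tiny)
                   / np.maximum(spec.power[de_sel].mean(axis=0), tiny))
    sd = ratio.std()
    z = (ratio - ratio.mean()) / sd if sd > 0 else np.zeros_like(ratio)
    return StateSeries(
        t=spec.t, ratio=z, is_theta=z >= threshold,
        bin_length=bin_length, threshold=threshold,
    )


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 3) -> np.ndarray:
    ny = fs / 2.0
    b, a = signal.butter(order, [lo / ny, hi / ny], btype="bandpass")
    return signal.filtfilt(b, a, x)


def segment_theta_cycles(
    x: np.ndarray | LFPSignal,
    fs: float | None = None,
    state: StateSeries | None = None,
    narrow: tuple[float, float] = (6.0, 10.0),
    broad: tuple[float, float] = (6.0, 40.0),
    channel: int = 0,
) -> pd.DataFrame:
    """Cycle-by-cycle theta segmentation.

    Candidate peaks/troughs are the extrema of the narrow-band (6-10 Hz)
    signal between its zero crossings; each is refined to the extremum of the
    broad-band (6-40 Hz) signal — which preserves theta's sawtooth shape —
    within the candidate's zero-crossing bracket.  Cycles are restricted to
    theta-state epochs when a state series is supplied.  The per-cycle
    asymmetry index is log2(ascending / descending duration).
    """
    if isinstance(x, LFPSignal):
        fs = x.fs
        x = x.channel(channel)
    if fs is None:
        raise ValueError("fs is required when passing a raw signal")
    xn = _bandpass(x, fs, *narrow)
    # gentle rolloff for the wide band: steeper filters clip the harmonics
    # that carry theta's sawtooth shape and shrink asymmetry estimates
    xb = _bandpass(x, fs, *broad, order=2)
    xn = xn - xn.mean()

    pos = xn > 0
    crossings = np.flatnonzero(np.diff(pos.astype(int)))
    if len(crossings) < 3:
        return pd.DataFrame(columns=THETA_CYCLE_COLUMNS)

    pad = int(round(0.1 * fs / narrow[0]))  # 10% of the slowest narrow period
    peaks: list[int] = []
    troughs: list[int] = []
    for z0, z1 in zip(crossings[:-1], crossings[1:]):
        seg = slice(z0 + 1, z1 + 1)
        lo = max(0, z0 + 1 - pad)
        hi = min(len(x), z1 + 1 + pad)
        if pos[z0 + 1]:  # positive half-wave: a peak
            peaks.append(lo + int(np.argmax(xb[lo:hi])))
        else:
            troughs.append(lo + int(np.argmin(xb[lo:hi])))

    peaks_arr = np.asarray(peaks)
    troughs_arr = np.asarray(troughs)
    rows = []
    for p0, p1 in zip(peaks_arr[:-1], peaks_arr[1:]):
        cand = troughs_arr[(troughs_arr > p0) & (troughs_arr < p1)]
        if len(cand) != 1:
            continue
        tr = int(cand[0])
        t_peak, t_trough, t_end = p0 / fs, tr / fs, p1 / fs
        dur_desc = t_trough - t_peak
        dur_asc = t_end - t_trough
        if dur_desc <= 0 or dur_asc <= 0:
            continue
        if state is not None and not state.theta_at(np.array([(t_peak + t_end) / 2]))[0]:
            continue
        rows.append({
            "t_peak": t_peak, "t_trough": t_trough, "t_end": t_end,
            "dur_desc": dur_desc, "dur_asc": dur_asc,
            "asymmetry": float(np.log2(dur_asc / dur_desc)),
        })
    return pd.DataFrame(rows, columns=THETA_CYCLE_COLUMNS)


def preprocess_lfp(
    lfp: LFPSignal, target_fs: float = 1000.0, notch_line: bool = True
) -> LFPSignal:
    """Anti-aliased decimation to <= ``target_fs`` plus a 60 Hz line notch.

    Recordings at kHz rates carry no information for the <= 400 Hz analyses
    here, so they are decimated before everything else.
    """
    x = lfp.samples
    fs = lfp.fs
    if fs > target_fs:
        q = int(fs // target_fs)
        if q > 1:
            x = signal.decimate(x, q, axis=1, ftype="fir", zero_phase=True)
            fs = fs / q
    if notch_line and fs > 150.0:
        b, a = signal.iirnotch(60.0, Q=30.0, fs=fs)
        x = signal.filtfilt(b, a, x, axis=1)
    return LFPSignal(samples=x, fs=fs, channel_ids=list(lfp.channel_ids), t0=lfp.t0)
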