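"""Heart-rate and heart-rate-variability metrics from single-lead ECG.

R peaks are found with a moving-average energy envelope (band-pass 5-25 Hz,
squared, 120 ms smoothing, adaptive threshold, 200 ms refractory); the R-R
series is cleaned of missed/extra/ectopic beats against a local median;
spectral powers come from the R-R series resampled at 4 Hz with Welch's
method (120 s segments, 50% overlap) integrated over the LF (0.04-0.15 Hz)
and HF (0.15-0.40 Hz) bands, and HFnu = HF/(HF+LF)*100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import interp1d

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

MIN_RR_MS = 200.0
MAX_RR_MS = 3000.0


@dataclass
class RRSeries:
    """R-R intervals in milliseconds with per-interval correction flags."""

    intervals: np.ndarray            # ms
    t_start: float = 0.0             # s, time of the first R peak
    corrected: np.ndarray = None     # bool per interval
    unreliable: bool = False

    def __post_init__(self):
        self.intervals = np.asarray(self.intervals, float)
        if self.corrected is None:
            self.corrected = np.zeros(len(self.intervals), bool)

    @property
    def beat_times(self) -> np.ndarray:
        """Times (s) of beats 1..n measured from the first R peak."""
        return self.t_start + np.cumsum(self.intervals) / 1000.0


@dataclass
class HRVMetrics:
    bpm: float
    sdnn: float                      # ms
    rmssd: float                     # ms
    hf_power: float = np.nan         # ms^2, 0.15-0.40 Hz
    lf_power: float = np.nan         # ms^2, 0.04-0.15 Hz
    hfnu: float = np.nan             # %


# --------------------------------------------------------------------------
# R-peak detection
# --------------------------------------------------------------------------

def detect_r_peaks(ecg, fs: float = None) -> np.ndarray:
    """Moving-average R-peak detector; returns sample indices.

    Accepts an :class:`~gammarep.synthetic.EcgTrace` or a raw array with
    ``fs``.  Scale invariant (threshold is relative to the envelope
    maximum); enforces a 200 ms refractory period.  A flat trace returns an
    empty result with a warning.
    """
    if hasattr(ecg, "samples"):
        x, fs = np.asarray(ecg.samples, float), ecg.fs
    else:
        x = np.asarray(ecg, float)
        if fs is None:
            raise ValueError("fs required for raw arrays")
    if fs < 250:
        raise ValueError("sampling rate must be >= 250 Hz for R detection")
    if np.ptp(x) == 0:
        warnings.warn("flat ECG trace: no R peaks")
        return np.array([], int)

    sos = signal.butter(3, [5.0, 25.0], btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, x)
    env = np.convolve(filt ** 2, np.ones(int(round(0.120 * fs))) / round(0.120 * fs),
                      mode="same")
    thr = 0.2 * np.percentile(env, 99.5)
    locs, _ = signal.find_peaks(env, height=thr, distance=int(round(0.2 * fs)))
    # refine each envelope peak to the raw-signal maximum nearby
    half = int(round(0.05 * fs))
    refined = []
    for lo in locs:
        a, b = max(0, lo - half), min(len(x), lo + half + 1)
        refined.append(a + int(np.argmax(x[a:b])))
    refined = np.unique(refined)
    # re-apply refractory after refinement
    keep = []
    for idx in refined:
        if not keep or (idx - keep[-1]) / fs >= 0.2:
            keep.append(idx)
    return np.asarray(keep, int)


def rr_from_peaks(peak_indices, fs: float) -> RRSeries:
    idx = np.asarray(peak_indices, float)
    if len(idx) < 2:
        raise ValueError("need at least 2 peaks")
    return RRSeries(intervals=np.diff(idx) / fs * 1000.0, t_start=idx[0] / fs)


# --------------------------------------------------------------------------
# R-R artifact correction
# --------------------------------------------------------------------------

def correct_rr(rr: RRSeries, window: int = 11) -> RRSeries:
    """Correct missed, extra and ectopic beats against a local median.

    Intervals longer than twice the local median are split into equal
    sub-intervals (missed beats); intervals shorter than half the local
    median are merged into their successor (extra beats); remaining values
    outside [0.5, 2] x local median are replaced by the local median.  Total
    duration is conserved by split/merge.  If more than 20% of intervals
    needed correction the series is flagged unreliable.
    """
    x = np.asarray(rr.intervals, float)
    if len(x) < 3:
        raise ValueError("need at least 3 intervals")
    win = window if window % 2 == 1 else window + 1

    def local_median(arr):
        if len(arr) < win:
            return np.full(len(arr), np.median(arr))
        med = signal.medfilt(arr, kernel_size=win)
        # medfilt zero-pads the edges; fall back to the global median there
        edge = win // 2
        med[:edge] = np.median(arr)
        med[-edge:] = np.median(arr)
        return med

    out = x.copy()
    flags = np.zeros(len(x), bool)
    n_corrected = 0
    for _ in range(5):                       # split/merge cascades need passes
        med = local_median(out)
        new, new_flags = [], []
        changed = False
        i = 0
        while i < len(out):
            v, m = out[i], med[i]
            if v >= 2.0 * m - 1e-9:          # missed beat(s): split
                parts = max(int(round(v / m)), 2)
                new.extend([v / parts] * parts)
                new_flags.extend([True] * parts)
                n_corrected += 1
                changed = True
            elif v < 0.5 * m and i + 1 < len(out):
                s = v + out[i + 1]
                if s < 1.5 * m:              # extra beat: the pair is one true beat
                    new.append(s)
                    new_flags.append(True)
                else:                        # premature/ectopic pair: redistribute
                    parts = max(int(round(s / m)), 2)
                    new.extend([s / parts] * parts)
                    new_flags.extend([True] * parts)
                n_corrected += 1
                changed = True
                i += 1
            elif not (0.5 * m <= v <= 2.0 * m) or not (MIN_RR_MS < v < MAX_RR_MS):
                new.append(m)                # ectopic: local-median replacement
                new_flags.append(True)
                n_corrected += 1
                changed = True
            else:
                new.append(v)
                new_flags.append(flags[i])
            i += 1
        out = np.asarray(new)
        flags = np.asarray(new_flags, bool)
        if not changed:
            break
    unreliable = n_corrected > 0.2 * len(x)
    if unreliable:
        warnings.warn(f"{n_corrected}/{len(x)} R-R intervals corrected; "
                      "HRV metrics flagged unreliable")
    return RRSeries(intervals=np.asarray(out), t_start=rr.t_start,
                    corrected=np.asarray(flags, bool), unreliable=unreliable)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def hrv_metrics(rr: RRSeries, resample_hz: float = 4.0,
                segment_s: float = 120.0) -> HRVMetrics:
    """BPM, SDNN, RMSSD and Welch-based LF/HF band powers with HFnu.

    Spectral metrics need >= 30 intervals spanning >= 120 s; shorter series
    return time-domain metrics only (spectral fields missing).
    """
    x = np.asarray(rr.intervals, float)
    if len(x) < 2:
        raise ValueError("need at least 2 intervals")
    bpm = 60000.0 / x.mean()
    sdnn = float(x.std(ddof=1)) if len(x) > 1 else 0.0
    rmssd = float(np.sqrt(np.mean(np.diff(x) ** 2))) if len(x) > 1 else 0.0

    span = x.sum() / 1000.0
    if len(x) < 30 or span < 120.0:
        return HRVMetrics(bpm=float(bpm), sdnn=sdnn, rmssd=rmssd)

    # resample the tachogram on a uniform grid and Welch-estimate the PSD
    t_beats = np.cumsum(x) / 1000.0
    interp = interp1d(t_beats, x, kind="cubic", bounds_error=False,
                      fill_value=(x[0], x[-1]))
    tg = np.arange(t_beats[0], t_beats[-1], 1.0 / resample_hz)
    series = signal.detrend(interp(tg))
    nperseg = min(len(series), int(segment_s * resample_hz))
    f, pxx = signal.welch(series, fs=resample_hz, nperseg=nperseg,
                          noverlap=nperseg // 2)

    def band_power(band):
        m = (f >= band[0]) & (f < band[1])
        return float(np.trapezoid(pxx[m], f[m])) if m.sum() > 1 else 0.0

    lf = band_power(LF_BAND)
    hf = band_power(HF_BAND)
    hfnu = 100.0 * hf / (hf + lf) if (hf + lf) > 0 else np.nan
    return HRVMetrics(bpm=float(bpm), sdnn=sdnn, rmssd=rmssd,
                      hf_power=hf, lf_power=lf, hfnu=float(hfnu))


def analyze_ecg(ecg) -> HRVMetrics:
    """Full chain: detect R peaks, correct the R-R series, compute metrics."""
    peaks = detect_r_peaks(ecg)
    rr = correct_rr(rr_from_peaks(peaks, ecg.fs))
    return hrv_metrics(rr)


def hrv_table(cohort) -> pd.DataFrame:
    """Per subject x window (rest, task) HRV table for a cohort with ECG."""
    rows = []
    for sub in cohort.subjects:
        for window, trace in (("rest", sub.ecg_rest), ("task", sub.ecg_task)):
            if trace is None:
                continue
            m = analyze_ecg(trace)
            rows.append({"subject_id": sub.subject_id, "group": sub.group,
                         "window": window, "bpm": m.bpm, "sdnn": m.sdnn,
                         "rmssd": m.rmssd, "hf": m.hf_power, "lf": m.lf_power,
                         "hfnu": m.hfnu})
    return pd.DataFrame(rows)
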