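"""Synthetic MEG + ECG cohort generator.

Emulates the data structure of a repetition-plasticity gamma experiment:
five interleaved drift-rate conditions x 90 trials per subject, an
uninterrupted first block of 137 trials, narrow-band induced gamma bursts
(35-100 Hz) riding on 1/f sensor noise, evoked onset transients, and a
single-lead ECG whose HF/(HF+LF) balance is coupled to the subject's latent
plasticity slope.

Two generation levels are provided:

``mode="epochs"``
    full multi-sensor time-domain trial epochs (sensors x samples at
    ``fs``), suitable for exercising the complete spectral pipeline
    (evoked subtraction, multitaper TFR, baseline normalization).

``mode="spectra"``
    single-trial baseline-normalized power spectra generated directly on
    the 2.5 Hz analysis grid with the same trial law.  Statistically this
    sits one (deterministic, well-tested) transform downstream of the
    epoch level and makes cohort-scale Monte-Carlo studies tractable.

The trial law (band-average relative gamma power, % over baseline)::

    P(n, c) = base * tuning(c) * gain_s * (1 + A*exp(-n/tau) + slope_s*n/100)

is the generative inverse of the dual-process model fitted downstream, so
parameter-recovery tests compare like with like.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import GeneratorConfig, analysis_freqs

GROUP_VSS = "VSS"
GROUP_CONTROL = "control"


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class TrialEpoch:
    """One trial's multi-sensor time series.

    ``t0`` is the time of the first sample relative to stimulus onset
    (t = 0 is onset).  ``trial_n`` is the 1-based overall trial order.
    """

    data: np.ndarray            # (n_sensors, n_samples)
    fs: float
    t0: float
    condition: float            # drift rate, deg/s
    trial_n: int
    subject_id: str
    group: str

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.shape[1]) / self.fs


@dataclass
class EcgTrace:
    """Single-lead ECG with ground-truth R-peak times (for tests)."""

    samples: np.ndarray
    fs: float
    true_r_times: np.ndarray    # seconds, strictly increasing

    def __post_init__(self):
        t = np.asarray(self.true_r_times, float)
        if t.size and (np.any(np.diff(t) <= 0) or t[-1] > len(self.samples) / self.fs):
            raise ValueError("true_r_times must be strictly increasing and inside the trace")


@dataclass
class SubjectSpectra:
    """Spectrum-level representation of one subject's trials."""

    subject_id: str
    group: str
    freqs: np.ndarray           # (n_freqs,)
    rel_power: np.ndarray       # (n_trials, n_freqs), % over baseline
    condition: np.ndarray       # (n_trials,)
    trial_n: np.ndarray         # (n_trials,), 1-based
    baseline_power: np.ndarray  # (n_trials,), a.u.


@dataclass
class SubjectData:
    subject_id: str
    group: str
    truth: dict
    epochs: Optional[list] = None
    spectra: Optional[SubjectSpectra] = None
    ecg_rest: Optional[EcgTrace] = None
    ecg_task: Optional[EcgTrace] = None


@dataclass
class CohortDataset:
    config: GeneratorConfig
    subjects: list
    seed: int

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame([s.truth for s in self.subjects])


# --------------------------------------------------------------------------
# generator law
# --------------------------------------------------------------------------

def relative_power_law(cfg: GeneratorConfig, condition: float, trial_n,
                       slope: float, subject_gain: float = 1.0) -> np.ndarray:
    """Expected band-average relative gamma power (% over baseline).

    ``slope`` is in ratio units per 100 trials; ``trial_n`` may be an array.
    """
    if condition not in cfg.gamma_power_tuning:
        raise ValueError(f"unknown condition {condition!r}")
    n = np.asarray(trial_n, float)
    if np.any(n < 1):
        raise ValueError("trial_n must be >= 1")
    trend = 1.0 + cfg.amp_early * np.exp(-n / cfg.tau_decay) + slope * n / 100.0
    # gamma power cannot go negative: floor the trend for extreme subjects
    # late in the session (outside the 137-trial analysis block for any
    # plausible latent slope)
    trend = np.maximum(trend, 0.05)
    return cfg.base_relative_power * cfg.gamma_power_tuning[condition] * subject_gain * trend


def _gamma_sigma(cfg: GeneratorConfig) -> float:
    # FWHM -> Gaussian sigma of the spectral bump
    return cfg.gamma_bandwidth / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _lognormal_unit_mean(rng, cv: float, size=None):
    """Lognormal draws with mean exactly 1 and coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    s2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=size)


# --------------------------------------------------------------------------
# time-domain synthesis
# --------------------------------------------------------------------------

def noise_psd(cfg: GeneratorConfig, freqs) -> np.ndarray:
    """One-sided PSD of the 1/f sensor noise (a.u.^2 / Hz)."""
    f = np.maximum(np.asarray(freqs, float), 1.0)
    return cfg.noise_scale / f ** cfg.noise_exponent


def synth_from_psd(n: int, fs: float, psd: np.ndarray, rng) -> np.ndarray:
    """Gaussian series of length ``n`` whose one-sided PSD equals ``psd``.

    ``psd`` is evaluated on ``np.fft.rfftfreq(n, 1/fs)``.
    """
    amp = np.sqrt(np.maximum(psd, 0.0) * fs * n / 2.0)
    z = (rng.standard_normal(len(amp)) + 1j * rng.standard_normal(len(amp)))
    z *= amp / np.sqrt(2.0)
    z[0] = 0.0
    if n % 2 == 0:
        z[-1] = z[-1].real * np.sqrt(2.0)
    return np.fft.irfft(z, n)


def _evoked_waveform(cfg: GeneratorConfig, condition: float, n_samples: int,
                     t0: float) -> np.ndarray:
    """Deterministic per-condition onset transient (two Gabor components)."""
    t = t0 + np.arange(n_samples) / cfg.fs
    ci = sorted(cfg.conditions).index(condition)
    amp = cfg.evoked_amp * (1.0 + 0.1 * ci)
    w = amp * np.exp(-((t - 0.10) ** 2) / (2 * 0.02 ** 2)) * np.cos(2 * np.pi * 10 * (t - 0.10))
    w += 0.6 * amp * np.exp(-((t - 0.18) ** 2) / (2 * 0.03 ** 2)) * np.cos(2 * np.pi * 7 * (t - 0.18))
    return w


def _burst_envelope(n: int, fs: float, ramp: float = 0.05) -> np.ndarray:
    """Cosine-squared on/off ramps at both ends of the burst window."""
    env = np.ones(n)
    nr = max(1, int(round(ramp * fs)))
    up = np.sin(np.linspace(0, np.pi / 2, nr)) ** 2
    env[:nr] = up
    env[-nr:] = up[::-1]
    return env


def simulate_trial_epoch(cfg: GeneratorConfig, subject_slope: float, trial_n: int,
                         condition: float, rng, subject_gain: float = 1.0,
                         freq_offset: float = 0.0, subject_id: str = "S00",
                         group: str = GROUP_CONTROL) -> TrialEpoch:
    """Simulate one multi-sensor trial epoch.

    Signal model: 1/f noise on all sensors, a deterministic evoked transient
    at stimulus onset, and a stimulus-window narrow-band gamma burst on the
    posterior sensor subset whose expected band-average relative power
    follows :func:`relative_power_law` on the dominant sensor.
    """
    cfg.validate()
    if trial_n < 1:
        raise ValueError("trial_n must be >= 1")
    if condition not in cfg.gamma_power_tuning:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    t0, t1 = cfg.epoch_window
    n_samples = int(round((t1 - t0) * cfg.fs))
    data = np.empty((cfg.n_sensors, n_samples))

    # 1/f background on every sensor
    psd_n = noise_psd(cfg, np.fft.rfftfreq(n_samples, 1 / cfg.fs))
    for s in range(cfg.n_sensors):
        data[s] = synth_from_psd(n_samples, cfg.fs, psd_n, rng)

    # evoked transient, identical for every trial of a condition
    evoked = _evoked_waveform(cfg, condition, n_samples, t0)
    gains = np.asarray(cfg.posterior_gains)
    for g, s in zip(gains, cfg.posterior_sensors):
        data[s] += g * evoked

    # gamma burst in the stimulation window [0, t1]
    target = relative_power_law(cfg, condition, trial_n, subject_slope, subject_gain)
    target *= _lognormal_unit_mean(rng, cfg.power_cv)
    fc = (cfg.gamma_freq_tuning[condition] + freq_offset
          + cfg.freq_drift * trial_n / 100.0
          + cfg.freq_jitter * rng.standard_normal())
    sig = _gamma_sigma(cfg)

    n_burst = int(round(t1 * cfg.fs))
    onset = int(round(-t0 * cfg.fs))
    # calibrate the burst PSD so that the band-average of (burst PSD / noise
    # PSD) over the +/-15 Hz analysis band equals the target relative power
    grid = analysis_freqs()
    fc_ref = (cfg.gamma_freq_tuning[condition] + freq_offset
              + cfg.freq_drift * (cfg.n_trials_total / 2) / 100.0)
    band = np.abs(grid - fc_ref) <= 15.0 + 1e-9
    bump_grid = np.exp(-((grid[band] - fc) ** 2) / (2 * sig ** 2))
    ratio = np.mean(bump_grid / noise_psd(cfg, grid[band]))
    env = _burst_envelope(n_burst, cfg.fs)
    ramp_factor = np.mean(env ** 2)
    q = (target / 100.0) / (ratio * ramp_factor)

    f_burst = np.fft.rfftfreq(n_burst, 1 / cfg.fs)
    psd_b = q * np.exp(-((f_burst - fc) ** 2) / (2 * sig ** 2))
    burst = synth_from_psd(n_burst, cfg.fs, psd_b, rng) * env
    for g, s in zip(gains, cfg.posterior_sensors):
        data[s, onset:onset + n_burst] += g * burst

    return TrialEpoch(data=data, fs=cfg.fs, t0=t0, condition=condition,
                      trial_n=trial_n, subject_id=subject_id, group=group)


# --------------------------------------------------------------------------
# spectrum-level synthesis
# --------------------------------------------------------------------------

def simulate_subject_spectra(cfg: GeneratorConfig, subject_id: str, group: str,
                             rng, latent: dict) -> SubjectSpectra:
    """Generate all single-trial relative spectra for one subject.

    ``latent`` must carry ``slope`` (per-100-trial), ``gain`` and
    ``freq_offset``; the condition sequence is drawn here.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    freqs = analysis_freqs()
    conds = np.repeat(sorted(cfg.conditions), cfg.n_trials_per_condition)
    order = rng.permutation(len(conds))
    conds = np.asarray(conds)[order]
    n_tr = len(conds)
    trial_n = np.arange(1, n_tr + 1)

    sig = _gamma_sigma(cfg)
    rel = rng.normal(0.0, cfg.spec_noise_sd, size=(n_tr, len(freqs)))
    mult = _lognormal_unit_mean(rng, cfg.power_cv, size=n_tr)
    jit = cfg.freq_jitter * rng.standard_normal(n_tr)

    for c in cfg.conditions:
        m = conds == c
        n = trial_n[m]
        p = relative_power_law(cfg, c, n, latent["slope"], latent["gain"])
        fc = (cfg.gamma_freq_tuning[c] + latent["freq_offset"]
              + cfg.freq_drift * n / 100.0 + jit[m])
        fc_ref = (cfg.gamma_freq_tuning[c] + latent["freq_offset"]
                  + cfg.freq_drift * (n_tr / 2) / 100.0)
        band = np.abs(freqs - fc_ref) <= 15.0 + 1e-9
        bump = np.exp(-((freqs[None, :] - fc[:, None]) ** 2) / (2 * sig ** 2))
        norm = bump[:, band].mean(axis=1)
        rel[m] += (p * mult[m] / norm)[:, None] * bump

    baseline = _lognormal_unit_mean(rng, cfg.baseline_cv, size=n_tr)
    return SubjectSpectra(subject_id=subject_id, group=group, freqs=freqs,
                          rel_power=rel, condition=conds.astype(float),
                          trial_n=trial_n, baseline_power=baseline)


# --------------------------------------------------------------------------
# ECG synthesis
# --------------------------------------------------------------------------

def simulate_ecg(cfg: GeneratorConfig, hfnu_target: float, duration: float,
                 rng) -> EcgTrace:
    """Synthetic single-lead ECG with controlled HF/LF autonomic balance.

    R-R intervals are a base interval modulated by an LF (0.1 Hz) and an HF
    (0.25 Hz) sinusoid plus white jitter; the HF/LF amplitude ratio steers
    the measured HFnu towards ``hfnu_target`` (in percent).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    h = np.clip(hfnu_target / 100.0, 0.01, 0.99)
    a_hf = cfg.rr_mod_depth * np.sqrt(h)
    a_lf = cfg.rr_mod_depth * np.sqrt(1.0 - h)
    ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)

    times = []
    t = float(rng.uniform(0.1, 0.4))
    while t < duration - 0.5:
        times.append(t)
        rr = cfg.mean_rr * (1.0 + a_lf * np.sin(2 * np.pi * 0.10 * t + ph1)
                            + a_hf * np.sin(2 * np.pi * 0.25 * t + ph2)
                            + 0.01 * rng.standard_normal())
        t += max(rr, 0.3)
    r_times = np.asarray(times)

    n = int(round(duration * cfg.ecg_fs))
    tt = np.arange(n) / cfg.ecg_fs
    ecg = 0.02 * rng.standard_normal(n)
    for rt in r_times:
        lo = max(0, int((rt - 0.3) * cfg.ecg_fs))
        hi = min(n, int((rt + 0.45) * cfg.ecg_fs))
        seg = tt[lo:hi]
        ecg[lo:hi] += np.exp(-((seg - rt) ** 2) / (2 * 0.008 ** 2))        # R
        ecg[lo:hi] -= 0.15 * np.exp(-((seg - rt - 0.035) ** 2) / (2 * 0.01 ** 2))  # S
        ecg[lo:hi] += 0.25 * np.exp(-((seg - rt - 0.25) ** 2) / (2 * 0.04 ** 2))   # T
    return EcgTrace(samples=ecg, fs=cfg.ecg_fs, true_r_times=r_times)


# --------------------------------------------------------------------------
# subjects and cohorts
# --------------------------------------------------------------------------

def _draw_latent(cfg: GeneratorConfig, group: str, rng) -> dict:
    mean = cfg.slope_vss if group == GROUP_VSS else cfg.slope_control
    slope = mean + cfg.slope_sd * rng.standard_normal()
    gain = _lognormal_unit_mean(rng, cfg.subject_gain_cv)
    freq_offset = cfg.subject_freq_sd * rng.standard_normal()
    # Gaussian copula links the (group-standardized) slope to the HFnu target
    z_slope = (slope - mean) / cfg.slope_sd if cfg.slope_sd > 0 else 0.0
    rho = cfg.hrv_coupling
    u = rho * z_slope + np.sqrt(max(0.0, 1 - rho ** 2)) * rng.standard_normal()
    from scipy.stats import norm
    hfnu_target = 100.0 * (0.2 + 0.6 * norm.cdf(u))
    return {"slope": slope, "gain": gain, "freq_offset": freq_offset,
            "hfnu_target": hfnu_target}


def simulate_subject(cfg: GeneratorConfig, subject_id: str, group: str, rng,
                     mode: str = "epochs", include_ecg: bool = True) -> SubjectData:
    """Simulate one subject: trials (epochs or spectra), ECG and latent truth."""
    if group not in (GROUP_VSS, GROUP_CONTROL):
        raise ValueError(f"group must be {GROUP_VSS!r} or {GROUP_CONTROL!r}")
    cfg.validate()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    latent = _draw_latent(cfg, group, rng)
    truth = {"subject_id": subject_id, "group": group,
             "slope_true": latent["slope"], "gain_true": latent["gain"],
             "freq_offset_true": latent["freq_offset"],
             "hfnu_target": latent["hfnu_target"]}

    sub = SubjectData(subject_id=subject_id, group=group, truth=truth)
    if mode == "spectra":
        sub.spectra = simulate_subject_spectra(cfg, subject_id, group, rng, latent)
    elif mode == "epochs":
        conds = np.repeat(sorted(cfg.conditions), cfg.n_trials_per_condition)
        conds = np.asarray(conds)[rng.permutation(len(conds))]
        sub.epochs = [
            simulate_trial_epoch(cfg, latent["slope"], int(i + 1), float(c), rng,
                                 subject_gain=latent["gain"],
                                 freq_offset=latent["freq_offset"],
                                 subject_id=subject_id, group=group)
            for i, c in enumerate(conds)
        ]
    else:
        raise ValueError("mode must be 'epochs' or 'spectra'")

    if include_ecg:
        sub.ecg_rest = simulate_ecg(cfg, latent["hfnu_target"], cfg.ecg_rest_duration, rng)
        sub.ecg_task = simulate_ecg(cfg, latent["hfnu_target"], cfg.ecg_task_duration, rng)
    return sub


def simulate_cohort(cfg: GeneratorConfig, mode: str = "spectra",
                    include_ecg: bool = False, seed=None) -> CohortDataset:
    """Simulate a full cohort; deterministic given (config, seed)."""
    cfg.validate()
    seed = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    n_total = cfg.n_vss + cfg.n_control
    if n_total < 1:
        raise ValueError("cohort must contain at least one subject")
    children = ss.spawn(n_total)
    subjects = []
    k = 0
    for i in range(cfg.n_vss):
        subjects.append(simulate_subject(cfg, f"vss{i + 1:02d}", GROUP_VSS,
                                         np.random.default_rng(children[k]),
                                         mode=mode, include_ecg=include_ecg))
        k += 1
    for i in range(cfg.n_control):
        subjects.append(simulate_subject(cfg, f"ctl{i + 1:02d}", GROUP_CONTROL,
                                         np.random.default_rng(children[k]),
                                         mode=mode, include_ecg=include_ecg))
        k += 1
    return CohortDataset(config=cfg, subjects=subjects, seed=seed)
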