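"""Configuration objects for the synthetic cohort generator and the pipeline.

Every printed analysis constant (normalization windows, 2/3-peak threshold,
80% sensor-selection rule, +/-15 Hz single-trial band, IQR coefficient k=2,
modelling window 15-137) lives here with its default, so the boundary
between study constants and package choices is auditable and overridable
from a single flat YAML file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: frequency grid used throughout the spectral analysis (Hz)
FREQ_MIN = 5.0
FREQ_MAX = 120.0
FREQ_STEP = 2.5

#: analysis windows relative to stimulus onset (s)
BASELINE_WINDOW = (-0.9, 0.0)
STIM_WINDOW = (0.3, 1.2)

#: gamma-response bands (Hz)
SENSOR_SELECTION_BAND = (35.0, 80.0)
GR_BAND = (35.0, 100.0)

#: single-trial integration half-band around the condition peak (Hz)
SINGLE_TRIAL_HALFBAND = 15.0

#: modelling window over the uninterrupted block (trial order numbers)
TRIAL_WINDOW = (15, 137)


def _default_freq_tuning() -> dict:
    # centre gamma frequency rises monotonically with grating drift rate
    return {0.0: 48.0, 0.6: 51.0, 1.2: 55.0, 3.6: 62.0, 6.0: 68.0}


def _default_power_tuning() -> dict:
    # bell-shaped drive tuning of gamma power, maximal at 1.2 deg/s
    return {0.0: 0.7, 0.6: 0.9, 1.2: 1.0, 3.6: 0.75, 6.0: 0.5}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic MEG + ECG cohort generator.

    The trial law for the band-average relative gamma power (in % over
    baseline) of subject ``s`` in condition ``c`` at overall trial ``n`` is::

        P(n, c) = base_relative_power * tuning(c)
                  * (1 + amp_early * exp(-n / tau_decay) + slope_s * n / 100)

    with ``slope_s`` drawn around the subject's group mean (``slope_vss`` or
    ``slope_control``, units: relative-power ratio per 100 trials).
    """

    n_vss: int = 26
    n_control: int = 27
    n_trials_per_condition: int = 90
    conditions: tuple = (0.0, 0.6, 1.2, 3.6, 6.0)
    fs: float = 1000.0
    epoch_window: tuple = (-1.2, 1.2)
    n_sensors: int = 24
    # indices of the posterior gradiometer subset that carries gamma signal
    posterior_sensors: tuple = (16, 17, 18, 19, 20, 21, 22, 23)
    # per-sensor amplitude gains of the gamma projection onto the posterior
    # subset: one dominant sensor, neighbours at 60-95% amplitude
    posterior_gains: tuple = (1.0, 0.95, 0.9, 0.85, 0.8, 0.6, 0.4, 0.2)

    gamma_freq_tuning: dict = field(default_factory=_default_freq_tuning)
    gamma_power_tuning: dict = field(default_factory=_default_power_tuning)
    gamma_bandwidth: float = 8.0       # FWHM of the gamma bump (Hz)

    tau_decay: float = 7.8             # trials; early-habituation time constant
    amp_early: float = 0.55            # early-excess amplitude (ratio units)
    slope_vss: float = 0.45            # ratio units per 100 trials
    slope_control: float = 0.19
    slope_sd: float = 0.20             # between-subject SD of the latent slope
    freq_drift: float = 0.43           # Hz per 100 trials
    freq_jitter: float = 1.5           # trial-to-trial SD of centre freq (Hz)
    subject_freq_sd: float = 2.5       # between-subject SD of centre freq (Hz)

    base_relative_power: float = 130.0  # % over baseline at tuning multiplier 1
    power_cv: float = 0.15             # lognormal trial-to-trial CV of gamma power
    spec_noise_sd: float = 30.0        # additive per-bin noise of relative spectra (%)
    subject_gain_cv: float = 0.2       # lognormal between-subject power gain CV
    baseline_cv: float = 0.25          # trial-to-trial CV of baseline band power

    noise_exponent: float = 1.0        # 1/f slope of the sensor noise
    noise_scale: float = 1.0           # PSD scale of the sensor noise (a.u.^2/Hz)
    evoked_amp: float = 3.0            # amplitude of the onset transient (a.u.)

    uninterrupted_block: int = 137     # trials available without a break

    ecg_fs: float = 250.0
    ecg_rest_duration: float = 300.0   # s, eyes-open rest
    ecg_task_duration: float = 390.0   # s, first task block
    hrv_coupling: float = 0.5          # target rank corr(latent slope, HFnu)
    mean_rr: float = 0.8               # s, base R-R interval
    rr_mod_depth: float = 0.05         # total LF+HF modulation depth (fraction)

    seed: int = 0

    def validate(self) -> None:
        if self.n_vss + self.n_control < 1:
            raise ValueError("cohort must contain at least one subject")
        if self.fs <= 0 or self.tau_decay <= 0:
            raise ValueError("fs and tau_decay must be positive")
        if set(self.gamma_freq_tuning) != set(self.conditions) or set(
            self.gamma_power_tuning
        ) != set(self.conditions):
            raise ValueError("tuning maps must cover exactly the configured conditions")
        conds = sorted(self.conditions)
        freqs = [self.gamma_freq_tuning[c] for c in conds]
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ValueError("gamma_freq_tuning must be strictly increasing in drift rate")
        powers = [self.gamma_power_tuning[c] for c in conds]
        if any(p <= 0 for p in powers):
            raise ValueError("gamma power multipliers must be positive")
        if max(self.gamma_power_tuning, key=self.gamma_power_tuning.get) != 1.2:
            raise ValueError("gamma_power_tuning must peak at 1.2 deg/s")
        if self.base_relative_power <= 0:
            raise ValueError("base_relative_power must be positive")
        if len(self.posterior_gains) != len(self.posterior_sensors):
            raise ValueError("one gain per posterior sensor required")
        if any(s >= self.n_sensors for s in self.posterior_sensors):
            raise ValueError("posterior sensor index out of range")

    @property
    def n_trials_total(self) -> int:
        return self.n_trials_per_condition * len(self.conditions)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        d["gamma_freq_tuning"] = {float(k): float(v) for k, v in self.gamma_freq_tuning.items()}
        d["gamma_power_tuning"] = {float(k): float(v) for k, v in self.gamma_power_tuning.items()}
        for key in ("epoch_window", "posterior_sensors", "posterior_gains"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("conditions", "epoch_window", "posterior_sensors", "posterior_gains"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def analysis_freqs():
    """The 2.5 Hz spectral grid shared by generator and analysis."""
    import numpy as np

    return np.arange(FREQ_MIN, FREQ_MAX + FREQ_STEP / 2, FREQ_STEP)
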