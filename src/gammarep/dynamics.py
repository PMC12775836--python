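"""Single-trial gamma dynamics: extraction, cleaning and repetition models.

Single-trial GR power is the mean relative power in a +/-15 Hz band around
the subject x condition average peak frequency; the single-trial frequency
is the power-weighted mean frequency in that band.  Series are cleaned by
the interquartile-range rule (k = 2), z-scored within subject x condition,
averaged over the cohort by trial order number, and fitted with the
dual-process model  y = A*exp(-n/tau) + B*n + C  and a continuous two-segment
broken-line model whose breakpoint estimates the habituation-to-potentiation
transition.  Per-subject plasticity is the mean OLS slope of z on trial
number over trials 15-137, averaged across conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize_scalar

from .config import SINGLE_TRIAL_HALFBAND, TRIAL_WINDOW
from .spectral import compute_gr_metrics, condition_average_spectrum


# --------------------------------------------------------------------------
# single-trial extraction
# --------------------------------------------------------------------------

def single_trial_gr(trial_spectra, freqs, condition_peak,
                    halfband=SINGLE_TRIAL_HALFBAND) -> pd.DataFrame:
    """Per-trial GR power and frequency in the +/-15 Hz band around the peak.

    ``trial_spectra`` is (n_trials, n_freqs) relative power in %.  Negative
    bins are floored at zero for the frequency weighting (the estimate stays
    inside the band); if the whole band is non-positive the frequency is
    missing while the power is still reported.
    """
    rel = np.atleast_2d(np.asarray(trial_spectra, float))
    freqs = np.asarray(freqs, float)
    band = np.abs(freqs - condition_peak) <= halfband + 1e-9
    if band.sum() < 2:
        raise ValueError("single-trial band must contain at least two bins")
    f = freqs[band]
    p = rel[:, band]
    st_power = p.mean(axis=1)
    w = np.clip(p, 0.0, None)
    tot = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        st_freq = (w * f).sum(axis=1) / tot
    st_freq[tot <= 0] = np.nan
    return pd.DataFrame({"st_power": st_power, "st_freq": st_freq})


def iqr_exclude(values, k=2.0) -> np.ndarray:
    """Kept flags by the interquartile-range rule with coefficient ``k``.

    A value is kept iff Q1 - k*IQR <= x <= Q3 + k*IQR, quartiles by linear
    interpolation.  Fewer than 4 values: all kept with a warning.
    """
    x = np.asarray(values, float)
    ok = np.isfinite(x)
    if ok.sum() < 4:
        warnings.warn("fewer than 4 values; IQR exclusion skipped")
        return np.ones_like(x, bool) & ok
    q1, q3 = np.percentile(x[ok], [25, 75])
    iqr = q3 - q1
    kept = (x >= q1 - k * iqr) & (x <= q3 + k * iqr)
    return kept & ok


def zscore(values, kept=None) -> np.ndarray:
    """z-transform over kept entries (sample SD); excluded entries get NaN."""
    x = np.asarray(values, float)
    kept = np.isfinite(x) if kept is None else np.asarray(kept, bool)
    z = np.full_like(x, np.nan)
    xs = x[kept]
    if xs.size < 2:
        warnings.warn("fewer than 2 kept values; z-scores undefined")
        return z
    sd = xs.std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance; z-scores undefined")
        return z
    z[kept] = (xs - xs.mean()) / sd
    return z


def single_trial_table(cohort, k_iqr=2.0, block=None,
                       per_condition_iqr=False) -> pd.DataFrame:
    """Tidy single-trial table for the uninterrupted block of a cohort.

    For every subject: condition-average spectra over all trials give the
    per-condition peak frequency; trials 1..block are reduced to st_power /
    st_freq; outliers are excluded by the IQR rule pooled over conditions
    per subject (or per condition if ``per_condition_iqr``); z-scores are
    computed within subject x condition over kept trials.
    """
    rows = []
    for sub in cohort.subjects:
        sp = sub.spectra
        if sp is None:
            raise ValueError("single_trial_table requires a spectra-mode cohort")
        nblock = cohort.config.uninterrupted_block if block is None else block
        in_block = sp.trial_n <= nblock
        sub_rows = []
        for c in sorted(set(sp.condition)):
            cmask = sp.condition == c
            avg = condition_average_spectrum(sp.rel_power[cmask], sp.freqs)
            met = compute_gr_metrics(avg)
            sel = cmask & in_block
            st = single_trial_gr(sp.rel_power[sel], sp.freqs, met.peak_freq)
            sub_rows.append(pd.DataFrame({
                "subject_id": sub.subject_id, "group": sub.group, "condition": c,
                "trialN": sp.trial_n[sel],
                "st_power": st["st_power"].to_numpy(),
                "st_freq": st["st_freq"].to_numpy(),
                "baseline_power": sp.baseline_power[sel],
                "peak_freq": met.peak_freq,
            }))
        df = pd.concat(sub_rows, ignore_index=True)
        if per_condition_iqr:
            df["kept"] = False
            for c, g in df.groupby("condition"):
                df.loc[g.index, "kept"] = iqr_exclude(g["st_power"], k=k_iqr)
        else:
            df["kept"] = iqr_exclude(df["st_power"], k=k_iqr)
        df["z"] = np.nan
        for c, g in df.groupby("condition"):
            df.loc[g.index, "z"] = zscore(g["st_power"], g["kept"])
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["subject_id", "trialN"]).reset_index(drop=True)


def grand_average_course(table: pd.DataFrame) -> pd.DataFrame:
    """Mean z per trial order number over subjects and conditions."""
    g = table.groupby("trialN")["z"]
    out = pd.DataFrame({"trialN": g.mean().index, "z_mean": g.mean().to_numpy(),
                        "n": g.count().to_numpy()})
    return out[out["n"] > 0].reset_index(drop=True)


# --------------------------------------------------------------------------
# dual-process model
# --------------------------------------------------------------------------

@dataclass
class DualProcessFit:
    A: float
    tau: float
    B: float
    C: float
    r2_adj: float
    tau_ci95: tuple = (np.nan, np.nan)
    flag: str = ""               # "", "tau_unidentifiable", "no_convergence"
    sse: float = np.nan


def _dual_model(n, A, tau, B, C):
    return A * np.exp(-n / tau) + B * n + C


def _line_fit(n, y):
    X = np.column_stack([n, np.ones_like(n)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef[0], coef[1], float(resid @ resid)


def fit_dual_process(trial_n, y, tau_grid=(2.0, 5.0, 10.0, 20.0, 40.0),
                     n_boot=0, seed=0) -> DualProcessFit:
    """Nonlinear least-squares fit of  y = A*exp(-n/tau) + B*n + C.

    Multi-start over a tau grid with A seeded from the early-minus-late mean
    difference and B, C from OLS on the last two thirds; deterministic given
    the data and the grid.  If the exponential term does not improve on a
    straight line the tau is flagged unidentifiable and B, C revert to the
    line fit.  Optional bootstrap (over trials) 95% CI for tau.
    """
    n = np.asarray(trial_n, float)
    y = np.asarray(y, float)
    ok = np.isfinite(n) & np.isfinite(y)
    n, y = n[ok], y[ok]
    if n.size < 20:
        raise ValueError("need at least 20 points to fit the dual-process model")

    late = n >= np.quantile(n, 1.0 / 3.0)
    b0, c0, _ = _line_fit(n[late], y[late])
    early_mask = n <= np.quantile(n, 0.1)
    a0 = float(y[early_mask].mean() - (b0 * n[early_mask] + c0).mean())
    if not np.isfinite(a0) or a0 == 0:
        a0 = np.std(y) or 1.0

    best = None
    for tau0 in tau_grid:
        try:
            popt, _ = curve_fit(_dual_model, n, y, p0=[a0, tau0, b0, c0],
                                bounds=([-np.inf, 1e-3, -np.inf, -np.inf],
                                        [np.inf, 1e4, np.inf, np.inf]),
                                maxfev=20000)
        except RuntimeError:
            continue
        sse = float(np.sum((y - _dual_model(n, *popt)) ** 2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        return DualProcessFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                              flag="no_convergence")
    popt, sse = best
    b_line, c_line, sse_line = _line_fit(n, y)
    sst = float(np.sum((y - y.mean()) ** 2))
    flag = ""
    if sse_line <= sse * (1 + 1e-9) or sse_line - sse <= 1e-12 * max(sst, 1e-300):
        # exponential adds nothing: tau unidentifiable, report the line
        flag = "tau_unidentifiable"
        popt = np.array([0.0, np.nan, b_line, c_line])
        sse = sse_line
        ci = (0.0, np.inf)
    else:
        ci = (np.nan, np.nan)
        if n_boot > 0:
            rng = np.random.default_rng(seed)
            taus = []
            for _ in range(n_boot):
                idx = rng.integers(0, n.size, n.size)
                try:
                    pb, _ = curve_fit(_dual_model, n[idx], y[idx],
                                      p0=popt, bounds=([-np.inf, 1e-3, -np.inf, -np.inf],
                                                       [np.inf, 1e4, np.inf, np.inf]),
                                      maxfev=5000)
                    taus.append(pb[1])
                except RuntimeError:
                    continue
            if len(taus) >= max(20, n_boot // 2):
                ci = tuple(np.percentile(taus, [2.5, 97.5]))
    p = 4
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    r2_adj = 1.0 - (1.0 - r2) * (n.size - 1) / max(n.size - p - 1, 1)
    return DualProcessFit(A=float(popt[0]), tau=float(popt[1]), B=float(popt[2]),
                          C=float(popt[3]), r2_adj=float(r2_adj), tau_ci95=ci,
                          flag=flag, sse=sse)


# --------------------------------------------------------------------------
# broken-line model
# --------------------------------------------------------------------------

@dataclass
class BrokenLineFit:
    psi: float
    slope_pre: float
    slope_post: float
    psi_ci95: tuple = (np.nan, np.nan)
    flag: str = ""
    sse: float = np.nan
    intercept: float = np.nan


def _broken_sse(n, y, psi):
    X = np.column_stack([np.ones_like(n), n, np.clip(n - psi, 0.0, None)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), coef


def broken_line_profile(n, y, breakpoints):
    """SSE of the continuous two-segment fit at each candidate breakpoint."""
    return np.array([_broken_sse(n, y, psi)[0] for psi in breakpoints])


def fit_broken_line(trial_n, y, n_boot=0, seed=0) -> BrokenLineFit:
    """Continuous two-segment linear fit with profiled breakpoint.

    The breakpoint is profiled over every interior integer trial number and
    refined by bounded continuous minimization around the best integer; an
    optional nonparametric bootstrap over trials yields the 95% CI.  A best
    breakpoint on the boundary of the profile grid is flagged.
    """
    n = np.asarray(trial_n, float)
    y = np.asarray(y, float)
    ok = np.isfinite(n) & np.isfinite(y)
    n, y = n[ok], y[ok]
    if n.size < 20:
        raise ValueError("need at least 20 points to fit the broken-line model")

    lo, hi = np.sort(np.unique(n))[1], np.sort(np.unique(n))[-2]
    grid = np.arange(np.ceil(lo), np.floor(hi) + 1)
    prof = broken_line_profile(n, y, grid)
    ibest = int(np.argmin(prof))
    flag = "boundary" if ibest in (0, len(grid) - 1) else ""
    a = grid[max(ibest - 1, 0)]
    b = grid[min(ibest + 1, len(grid) - 1)]
    if a < b:
        res = minimize_scalar(lambda p: _broken_sse(n, y, p)[0], bounds=(a, b),
                              method="bounded", options={"xatol": 1e-4})
        psi = float(res.x)
    else:
        psi = float(grid[ibest])
    sse, coef = _broken_sse(n, y, psi)
    # degenerate single line: breakpoint carries no information
    _, _, sse_line = _line_fit(n, y)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sse_line <= sse * (1 + 1e-9) + 1e-12 * max(sst, 1e-300):
        flag = flag or "weak_break"

    ci = (np.nan, np.nan)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        psis = []
        for _ in range(n_boot):
            idx = rng.integers(0, n.size, n.size)
            nb, yb = n[idx], y[idx]
            if np.unique(nb).size < 5:
                continue
            pb = broken_line_profile(nb, yb, grid)
            psis.append(grid[int(np.argmin(pb))])
        if len(psis) >= max(20, n_boot // 2):
            ci = tuple(np.percentile(psis, [2.5, 97.5]))
            if ci[1] - ci[0] > 0.8 * (grid[-1] - grid[0]):
                flag = flag or "weak_break"
    return BrokenLineFit(psi=psi, slope_pre=float(coef[1]),
                         slope_post=float(coef[1] + coef[2]), psi_ci95=ci,
                         flag=flag, sse=sse, intercept=float(coef[0]))


# --------------------------------------------------------------------------
# per-subject plasticity slopes
# --------------------------------------------------------------------------

def subject_slope(table: pd.DataFrame, trial_window=TRIAL_WINDOW,
                  min_trials=5) -> pd.DataFrame:
    """Per-subject plasticity slope: OLS of z on trialN per condition,
    averaged (unweighted) across conditions, inside ``trial_window``.

    Conditions with fewer than ``min_trials`` usable trials are omitted from
    the average and flagged in ``n_conditions_used``.  Returned ``coef`` is
    in z-units per trial.
    """
    lo, hi = trial_window
    sel = table[(table["trialN"] >= lo) & (table["trialN"] <= hi)
                & table["kept"] & np.isfinite(table["z"])]
    rows = []
    for (sid, grp), g in sel.groupby(["subject_id", "group"], sort=True):
        coefs = {}
        for c, gc in g.groupby("condition"):
            if len(gc) < min_trials:
                warnings.warn(f"{sid}: condition {c} has <{min_trials} usable trials; omitted")
                continue
            slope, _, _ = _line_fit(gc["trialN"].to_numpy(float), gc["z"].to_numpy(float))
            coefs[c] = slope
        rows.append({"subject_id": sid, "group": grp,
                     "coef": float(np.mean(list(coefs.values()))) if coefs else np.nan,
                     "n_conditions_used": len(coefs),
                     "per_condition_coefs": coefs})
    return pd.DataFrame(rows)
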