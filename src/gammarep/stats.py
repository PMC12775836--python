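"""Group-level inferential battery.

Trial-level linear mixed models (random subject and condition intercepts
and slopes, Satterthwaite degrees of freedom) are fitted with lme4 +
lmerTest through an Rscript subprocess — the standard stack for this model
class; everything else (mixed ANOVA with Greenhouse-Geisser correction and
partial eta squared, rank tests, Spearman correlations, summary-statistic
t-tests, noncentral power/sensitivity calculators) runs on scipy/pingouin.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

GROUP_LEVELS = ["VSS", "control"]  # VSS is the reference level

# formula ladders: simplified stepwise when the random structure is singular
_LADDERS = {
    "power": [
        "y ~ trialN * group + (1 + trialN | subject) + (1 + trialN | condition)",
        "y ~ trialN * group + (1 + trialN | subject) + (1 | condition)",
        "y ~ trialN * group + (1 + trialN | subject)",
        "y ~ trialN * group + (1 | subject)",
        "y ~ trialN * group",
    ],
    "baseline": [
        "y ~ trialN * group + (1 + trialN | subject)",
        "y ~ trialN * group + (1 | subject)",
        "y ~ trialN * group",
    ],
    "freq": [
        "y ~ trialN + (1 + trialN | subject) + (1 | condition)",
        "y ~ trialN + (1 + trialN | subject)",
        "y ~ trialN + (1 | subject)",
        "y ~ trialN",
    ],
}

_R_SCRIPT = r"""
suppressMessages({library(lme4); library(lmerTest); library(jsonlite)})
args <- commandArgs(trailingOnly = TRUE)
dat <- read.csv(args[1])
meta <- fromJSON(args[2])
formulas <- meta$formulas
out <- list()
for (rep in unique(dat$replicate)) {
  d <- dat[dat$replicate == rep, ]
  d$group <- factor(d$group, levels = meta$group_levels)
  d$subject <- factor(d$subject)
  d$condition <- factor(d$condition)
  fit <- NULL; used <- NA; singular <- NA; fallback <- NULL; fb_used <- NA
  for (f in formulas) {
    if (!grepl("\\|", f)) {
      m <- tryCatch(lm(as.formula(f), data = d), error = function(e) NULL)
      if (!is.null(m)) { fit <- m; used <- f; singular <- FALSE; break }
      next
    }
    m <- tryCatch(suppressMessages(suppressWarnings(
           lmerTest::lmer(as.formula(f), data = d, REML = meta$reml))),
         error = function(e) NULL)
    if (is.null(m)) next
    if (!isSingular(m, tol = 1e-4)) { fit <- m; used <- f; singular <- FALSE; break }
    if (is.null(fallback)) { fallback <- m; fb_used <- f }
  }
  if (is.null(fit) && !is.null(fallback)) { fit <- fallback; used <- fb_used; singular <- TRUE }
  if (is.null(fit)) {
    out[[length(out) + 1]] <- list(replicate = rep, error = "no model converged")
    next
  }
  co <- summary(fit)$coefficients
  if (inherits(fit, "lm") && !inherits(fit, "lmerMod")) {
    terms <- rownames(co)
    res <- list(replicate = rep, formula = used, singular = FALSE,
                terms = terms, estimate = unname(co[, 1]), se = unname(co[, 2]),
                df = rep(fit$df.residual, length(terms)),
                t = unname(co[, 3]), p = unname(co[, 4]),
                aic = AIC(fit), bic = BIC(fit), loglik = as.numeric(logLik(fit)))
  } else {
    res <- list(replicate = rep, formula = used, singular = singular,
                terms = rownames(co), estimate = unname(co[, "Estimate"]),
                se = unname(co[, "Std. Error"]), df = unname(co[, "df"]),
                t = unname(co[, "t value"]), p = unname(co[, "Pr(>|t|)"]),
                aic = AIC(fit), bic = BIC(fit), loglik = as.numeric(logLik(fit)))
    if (meta$n_boot > 0) {
      bt <- tryCatch(suppressMessages(suppressWarnings(
              bootMer(fit, fixef, nsim = meta$n_boot, seed = meta$boot_seed))),
            error = function(e) NULL)
      if (!is.null(bt)) {
        ci <- apply(bt$t, 2, quantile, probs = c(0.025, 0.975), na.rm = TRUE)
        res$boot_terms <- colnames(bt$t)
        res$boot_lo <- unname(ci[1, ]); res$boot_hi <- unname(ci[2, ])
        ix <- which(colnames(bt$t) == "trialN")
        jx <- grep("^trialN:group", colnames(bt$t))
        if (length(ix) == 1 && length(jx) == 1) {
          s <- bt$t[, ix] + bt$t[, jx]
          res$boot_sum_lo <- unname(quantile(s, 0.025, na.rm = TRUE))
          res$boot_sum_hi <- unname(quantile(s, 0.975, na.rm = TRUE))
        }
      }
    }
  }
  out[[length(out) + 1]] <- res
}
cat(toJSON(out, auto_unbox = TRUE, digits = 12, na = "null"))
"""


@dataclass
class LMMResult:
    fixed: pd.DataFrame          # term, estimate, se, df, t, p
    formula: str
    singular: bool
    aic: float
    bic: float
    loglik: float
    per100: dict = field(default_factory=dict)
    boot_ci: dict = field(default_factory=dict)

    def term(self, name) -> pd.Series:
        m = self.fixed[self.fixed["term"] == name]
        if m.empty:
            raise KeyError(name)
        return m.iloc[0]


def _require_rscript() -> str:
    exe = shutil.which("Rscript")
    if exe is None:
        raise RuntimeError("Rscript (with lme4/lmerTest) is required for mixed models")
    return exe


def _lmer_batch(frames, ladder, reml=True, n_boot=0, boot_seed=1):
    """Fit the formula ladder once per frame in a single R session."""
    exe = _require_rscript()
    tall = []
    for i, df in enumerate(frames):
        d = df.copy()
        d["replicate"] = i
        tall.append(d)
    tall = pd.concat(tall, ignore_index=True)
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        data_path = tmp / "data.csv"
        meta_path = tmp / "meta.json"
        script = tmp / "fit.R"
        tall.to_csv(data_path, index=False)
        meta_path.write_text(json.dumps({
            "formulas": ladder, "group_levels": GROUP_LEVELS,
            "reml": bool(reml), "n_boot": int(n_boot), "boot_seed": int(boot_seed),
        }))
        script.write_text(_R_SCRIPT)
        proc = subprocess.run([exe, "--vanilla", str(script), str(data_path), str(meta_path)],
                              capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(f"lmer backend failed:\n{proc.stderr[-2000:]}")
        payload = json.loads(proc.stdout)

    results = []
    for res in payload:
        if "error" in res:
            raise RuntimeError(f"LMM did not converge: {res['error']}")
        fixed = pd.DataFrame({k: np.atleast_1d(res[k])
                              for k in ("estimate", "se", "df", "t", "p")})
        fixed.insert(0, "term", np.atleast_1d(res["terms"]))
        out = LMMResult(fixed=fixed, formula=res["formula"],
                        singular=bool(res["singular"]), aic=res["aic"],
                        bic=res["bic"], loglik=res["loglik"])
        if "trialN" in set(fixed["term"]):
            est = dict(zip(fixed["term"], fixed["estimate"]))
            out.per100["trialN"] = 100.0 * est["trialN"]
            inter = [t for t in est if t.startswith("trialN:group")]
            if inter:
                out.per100["vss_slope"] = 100.0 * est["trialN"]
                out.per100["control_slope"] = 100.0 * (est["trialN"] + est[inter[0]])
                out.per100["interaction"] = 100.0 * est[inter[0]]
        if "boot_terms" in res:
            terms = np.atleast_1d(res["boot_terms"])
            lo = np.atleast_1d(res["boot_lo"])
            hi = np.atleast_1d(res["boot_hi"])
            out.boot_ci = {t: (float(l), float(h)) for t, l, h in zip(terms, lo, hi)}
            if "boot_sum_lo" in res:
                out.boot_ci["control_slope"] = (res["boot_sum_lo"], res["boot_sum_hi"])
        results.append(out)
    return results


def _prepare_lmm_frame(table: pd.DataFrame, response: str) -> pd.DataFrame:
    cols = {"power": "st_power_ratio", "freq": "st_freq", "baseline": "baseline_power"}
    if response not in cols:
        raise ValueError("response must be one of 'power', 'freq', 'baseline'")
    df = table.copy()
    if response == "power" and "st_power_ratio" not in df:
        # trial-level model runs on relative power in ratio units (%/100) so
        # per-100-trial effects read directly as change relative to baseline
        df["st_power_ratio"] = df["st_power"] / 100.0
    y = df[cols[response]]
    df = pd.DataFrame({
        "y": y.to_numpy(float),
        "trialN": df["trialN"].to_numpy(float),
        "group": df["group"].to_numpy(),
        "subject": df["subject_id"].to_numpy(),
        "condition": df["condition"].to_numpy(),
    })
    df = df[np.isfinite(df["y"])]
    if df["group"].nunique() < 2 and response != "freq":
        raise ValueError("need both groups in the trial table")
    return df


def fit_repetition_lmm(table: pd.DataFrame, response: str = "power",
                       reml: bool = True, n_boot: int = 0,
                       boot_seed: int = 1) -> LMMResult:
    """Trial-level mixed model of repetition effects.

    response='power':    y ~ trialN*group + (1+trialN|subject) + (1+trialN|condition)
    response='baseline': y ~ trialN*group + (1+trialN|subject)
    response='freq':     y ~ trialN + (1+trialN|subject) + (1|condition)

    Singular random-effect fits fall down a simplification ladder (condition
    slope dropped first, then the condition intercept).  Fixed-effect t
    statistics use Satterthwaite denominator dfs; ``per100`` holds the
    per-100-trial slopes (VSS is the reference group level).
    """
    frame = _prepare_lmm_frame(table, response)
    return _lmer_batch([frame], _LADDERS[response], reml=reml,
                       n_boot=n_boot, boot_seed=boot_seed)[0]


def fit_repetition_lmm_batch(tables, response: str = "power", reml: bool = True):
    """Fit the same repetition model to many trial tables in one R session."""
    frames = [_prepare_lmm_frame(t, response) for t in tables]
    return _lmer_batch(frames, _LADDERS[response], reml=reml)


def compare_trial_predictors(table: pd.DataFrame, response: str = "power") -> dict:
    """Is single-trial power driven by overall trial order or by the number
    of stimulus-specific repetitions?

    Fits the repetition model twice (maximum likelihood), once with the
    overall trial order number and once with the within-condition repetition
    count as the trial predictor, and compares AIC/BIC/logLik.
    """
    base = table.copy().sort_values(["subject_id", "condition", "trialN"])
    base["repN"] = base.groupby(["subject_id", "condition"]).cumcount() + 1.0
    t1 = base.copy()
    t2 = base.copy()
    t2["trialN"] = t2["repN"]
    r_trial, r_rep = fit_repetition_lmm_batch([t1, t2], response=response, reml=False)
    d_aic = r_trial.aic - r_rep.aic
    return {
        "trialN": r_trial, "repN": r_rep,
        "delta_aic": d_aic, "delta_bic": r_trial.bic - r_rep.bic,
        "delta_loglik": r_trial.loglik - r_rep.loglik,
        "preferred": "trialN" if d_aic < 0 else ("repN" if d_aic > 0 else "tie"),
    }


# --------------------------------------------------------------------------
# mixed ANOVA with Greenhouse-Geisser correction
# --------------------------------------------------------------------------

def mixed_anova_gg(subject_table: pd.DataFrame, dv: str, within: str = "condition",
                   subject: str = "subject_id", between: str = "group",
                   covariate: str | None = None) -> pd.DataFrame:
    """Mixed ANOVA (between group x within condition) with G-G correction.

    Returns one row per effect with F, df1, df2, p, gg_epsilon, p_gg and
    partial eta squared.  Subjects with an incomplete within-factor grid are
    dropped with a warning.  A covariate (e.g. normalized age) is removed by
    within-cell residualization before the ANOVA.
    """
    import pingouin as pg

    df = subject_table[[subject, between, within, dv] +
                       ([covariate] if covariate else [])].copy()
    df = df[np.isfinite(df[dv])]
    n_levels = df[within].nunique()
    counts = df.groupby(subject)[within].nunique()
    bad = counts[counts < n_levels].index
    if len(bad):
        warnings.warn(f"dropping {len(bad)} subjects with incomplete condition grids")
        df = df[~df[subject].isin(bad)]

    if covariate:
        cov = df[covariate].to_numpy(float)
        yv = df[dv].to_numpy(float)
        cell = df[between].astype(str) + "/" + df[within].astype(str)
        yc = yv - pd.Series(yv).groupby(cell.values).transform("mean").to_numpy()
        xc = cov - pd.Series(cov).groupby(cell.values).transform("mean").to_numpy()
        b = (xc @ yc) / (xc @ xc) if (xc @ xc) > 0 else 0.0
        df[dv] = yv - b * (cov - cov.mean())

    aov = pg.mixed_anova(data=df, dv=dv, within=within, subject=subject,
                         between=between, correction=True, effsize="np2")

    def col(*names):
        for nm in names:
            if nm in aov:
                return aov[nm]
        return pd.Series(np.nan, index=aov.index)

    out = pd.DataFrame({
        "effect": aov["Source"],
        "F": aov["F"], "df1": aov["DF1"], "df2": aov["DF2"],
        "p": col("p_unc", "p-unc"),
        "gg_epsilon": col("eps"),
        "p_gg": col("p_GG_corr", "p-GG-corr"),
        "eta_p2": aov["np2"],
    })
    # the G-G correction only applies to within-subject effects; elsewhere
    # the corrected p equals the uncorrected one
    out["p_gg"] = out["p_gg"].fillna(out["p"])
    return out


# --------------------------------------------------------------------------
# rank tests, correlations, summary-statistic t-tests
# --------------------------------------------------------------------------

def rank_tests(x, y) -> dict:
    """Mann-Whitney U with normal-approximation Z (tie corrected) and
    effect sizes r = Z/sqrt(n1+n2) and the Cohen's d equivalent."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 observations per sample")
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    nn = n1 + n2
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (nn * (nn - 1.0)) if nn > 1 else 0.0
    var = n1 * n2 / 12.0 * (nn + 1.0 - tie_term)
    if var <= 0:
        return {"U": u1, "Z": 0.0, "p": 1.0, "r": 0.0, "d": 0.0}
    z = (u1 - mu) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    r = z / np.sqrt(nn)
    d = 2.0 * r / np.sqrt(max(1.0 - r * r, 1e-12))
    return {"U": float(u1), "Z": float(z), "p": float(min(p, 1.0)),
            "r": float(r), "d": float(d)}


def spearman_corr(x, y) -> dict:
    """Spearman rank correlation with t-approximation p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.unique(x[ok]).size < 2 or np.unique(y[ok]).size < 2:
        raise ValueError("constant input: correlation undefined")
    r, p = stats.spearmanr(x[ok], y[ok])
    return {"R": float(r), "p": float(p), "n": int(ok.sum())}


def summary_t(mode: str, mean1, sd1, n1, mean2=None, sd2=None, n2=None,
              mu0: float = 0.0) -> dict:
    """t statistic from summary statistics.

    mode='two_sample_pooled': pooled-variance two-sample t.
    mode='one_sample': t for mean1 against mu0.
    """
    if mode == "two_sample_pooled":
        if None in (mean2, sd2, n2):
            raise ValueError("two-sample mode needs both summaries")
        if sd1 <= 0 or sd2 <= 0 or n1 < 2 or n2 < 2:
            raise ValueError("SDs must be positive and n >= 2")
        df = n1 + n2 - 2
        sp = np.sqrt(((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df)
        t = (mean1 - mean2) / (sp * np.sqrt(1.0 / n1 + 1.0 / n2))
    elif mode == "one_sample":
        if sd1 <= 0 or n1 < 2:
            raise ValueError("SD must be positive and n >= 2")
        df = n1 - 1
        t = (mean1 - mu0) / (sd1 / np.sqrt(n1))
    else:
        raise ValueError("mode must be 'two_sample_pooled' or 'one_sample'")
    p = 2.0 * stats.t.sf(abs(t), df)
    return {"t": float(t), "df": int(df), "p": float(p)}


# --------------------------------------------------------------------------
# power and sensitivity
# --------------------------------------------------------------------------

def power_two_sample_t(d: float, n1: int, n2: int, alpha: float = 0.05,
                       sided: str = "one") -> float:
    """Power of a two-sample t-test via the noncentral t distribution.

    ncp = d * sqrt(n1*n2/(n1+n2)), df = n1+n2-2.  ``sided`` in
    {'one', 'two'}; the directional test reproduces the printed 84% power
    for d=0.74 with n=26/27 at alpha=0.05.
    """
    if d < 0 or n1 < 2 or n2 < 2:
        raise ValueError("need d >= 0 and n >= 2 per group")
    df = n1 + n2 - 2
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    if sided == "one":
        tcrit = stats.t.ppf(1 - alpha, df)
        return float(stats.nct.sf(tcrit, df, ncp))
    if sided == "two":
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
    raise ValueError("sided must be 'one' or 'two'")


def min_detectable_eta_p2(df1: int, df2: int, N: int, alpha: float = 0.05,
                          power: float = 0.80) -> float:
    """Smallest partial eta squared detectable by an F(df1, df2) test.

    Solves the noncentrality lambda at which the test reaches ``power``,
    converts via f^2 = lambda/N and eta_p2 = f^2/(1+f^2).
    """
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    fcrit = stats.f.ppf(1 - alpha, df1, df2)

    def gap(lam):
        return stats.ncf.sf(fcrit, df1, df2, lam) - power

    if gap(1e-9) > 0 or gap(1e4) < 0:
        raise RuntimeError("no noncentrality solution in (0, 1e4)")
    lam = optimize.brentq(gap, 1e-9, 1e4, xtol=1e-10)
    f2 = lam / N
    return float(f2 / (1.0 + f2))
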