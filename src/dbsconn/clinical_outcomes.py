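"""Clinical outcome statistics for the staggered-onset DBS trial.

Covers the trial's analysis surface: percentage reductions and responder
classification (>= 35% YBOCS, >= 50% MADRS), the blinded-phase two-sample
t-test on change scores, a longitudinal linear mixed-effects model with
crossed random intercepts for participant and timepoint, the paired
additive-CBT comparison, and a Shapiro-Wilk normality check.

Conventions
-----------
* Change scores are oriented so that positive = improvement (score
  reduction), matching "YBOCS reduction" throughout.
* The two-sample t-test is Student (pooled variance) by default; Welch is
  available via ``method="welch"``.
* The mixed model implements the formula as literally written —
  ``(1|ID) + (1|TimeSinceDBS)`` — i.e. two crossed random intercepts; a
  random-slope-per-participant variant is available behind a flag.
* Gender enters as a two-level factor with reference level female
  (alphabetical).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats


class OutcomeError(ValueError):
    """Invalid input to a clinical-outcome computation."""


# ---------------------------------------------------------------------------
# elementary summaries
# ---------------------------------------------------------------------------

def percent_reduction(baseline, endpoint):
    """Percentage reduction 100 * (baseline - endpoint) / baseline.

    Accepts scalars or arrays; negative values mean worsening.  A zero
    baseline has no defined percentage change and raises.
    """
    b = np.asarray(baseline, dtype=float)
    e = np.asarray(endpoint, dtype=float)
    if np.any(b <= 0):
        raise OutcomeError("percent reduction requires baseline > 0")
    out = 100.0 * (b - e) / b
    return float(out) if out.ndim == 0 else out


def classify_responders(pct_reductions, threshold: float) -> tuple[np.ndarray, int]:
    """Responder flags (pct >= threshold, inclusive) and the responder count."""
    pct = np.asarray(pct_reductions, dtype=float)
    if pct.size == 0:
        raise OutcomeError("no percentage reductions supplied")
    if not (0 < threshold <= 100):
        raise OutcomeError("threshold must lie in (0, 100]")
    flags = pct >= threshold
    return flags, int(flags.sum())


@dataclass(frozen=True)
class OutcomeSummary:
    """Mean and dispersion of a cohort-level quantity.

    Both the sample (n-1) and population (n) standard deviations are
    reported because published cohort tables mix the two conventions.
    """

    mean: float
    sd: float        # sample, n-1 denominator
    sd_pop: float    # population, n denominator
    sem: float
    n: int
    ci95: tuple[float, float]
    degenerate: bool = False  # n == 1: dispersion undefined, reported as 0


def cohort_summary(values) -> OutcomeSummary:
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise OutcomeError("empty input")
    n = int(vals.size)
    mean = float(vals.mean())
    if n == 1:
        return OutcomeSummary(mean, 0.0, 0.0, 0.0, 1, (mean, mean), degenerate=True)
    sd = float(vals.std(ddof=1))
    sd_pop = float(vals.std(ddof=0))
    sem = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    return OutcomeSummary(mean, sd, sd_pop, sem, n,
                          (mean - tcrit * sem, mean + tcrit * sem))


# ---------------------------------------------------------------------------
# blinded-phase comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: float
    mean_diff: float
    ci95: tuple[float, float]
    method: str
    degenerate: bool = False


def blinded_phase_comparison(change_active, change_sham,
                             method: str = "student") -> TTestResult:
    """Two-sample t-test on blinded-phase change scores (active vs sham).

    ``change`` is baseline score minus end-of-blinded score, so positive
    means improvement and a positive mean difference favours active
    stimulation.  Student (pooled) by default, Welch behind the flag.
    """
    a = np.asarray(change_active, dtype=float)
    b = np.asarray(change_sham, dtype=float)
    if a.size < 2 or b.size < 2:
        raise OutcomeError("each group needs n >= 2")
    if method not in ("student", "welch"):
        raise OutcomeError("method must be 'student' or 'welch'")
    diff = float(a.mean() - b.mean())
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
        return TTestResult(t, p, a.size + b.size - 2, diff, (diff, diff),
                           method, degenerate=True)
    equal_var = method == "student"
    tt = stats.ttest_ind(a, b, equal_var=equal_var)
    df = float(tt.df)
    if equal_var:
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
        se = np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    else:
        se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    tcrit = stats.t.ppf(0.975, df)
    return TTestResult(float(tt.statistic), float(tt.pvalue), df, diff,
                       (diff - tcrit * se, diff + tcrit * se), method)


def blinded_changes(visits: pd.DataFrame, outcome: str = "ybocs"
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-participant blinded-phase change scores split by randomised arm.

    Change = baseline score minus the last blinded-phase score (positive =
    improvement).
    """
    active, sham = [], []
    for pid, sub in visits.groupby("participant_id"):
        sub = sub.sort_values("visit_day")
        base = sub.loc[sub["phase"] == "baseline", outcome]
        end = sub.loc[sub["phase"] == "blinded", outcome]
        if base.empty or end.empty:
            raise OutcomeError(f"participant {pid}: missing baseline or blinded visit")
        change = float(base.iloc[0]) - float(end.iloc[-1])
        arm = sub["arm"].iloc[0]
        (active if arm == "active" else sham).append(change)
    return np.asarray(active), np.asarray(sham)


# ---------------------------------------------------------------------------
# longitudinal mixed model
# ---------------------------------------------------------------------------

@dataclass
class MixedModelResult:
    coefficients: pd.DataFrame   # term, estimate, se, tvalue, pvalue
    lrt_chi2: float
    lrt_df: int
    lrt_p: float
    converged: bool
    fallback: str | None         # None, or a note naming the fallback used
    n_obs: int
    n_participants: int
    notes: str

    @property
    def time_coefficient(self) -> float:
        row = self.coefficients.loc[self.coefficients["term"] == "time_since_dbs"]
        return float(row["estimate"].iloc[0])


def _prepare_longitudinal(visits: pd.DataFrame, participants: pd.DataFrame,
                          outcome: str) -> pd.DataFrame:
    if outcome not in ("ybocs", "madrs"):
        raise OutcomeError("outcome must be 'ybocs' or 'madrs'")
    post = visits[visits["visit_day"] >= 0].copy()
    if not (post["phase"] == "open").any():
        raise OutcomeError("no open-phase visits present")
    cols = ["participant_id", "age", "gender"]
    base_col = f"baseline_{outcome}"
    df = post.merge(participants[cols + [base_col]], on="participant_id", how="left")
    df = df.rename(columns={outcome: "score", base_col: "baseline"})
    df["time_since_dbs"] = df["visit_day"].astype(float)
    # scaled copy (per 100 days) keeps the optimiser well conditioned; the
    # reported coefficient is converted back to points per day
    df["time_c"] = df["time_since_dbs"] / _TIME_SCALE
    return df.dropna(subset=["score", "age", "gender", "baseline"])


_TIME_SCALE = 100.0  # days per unit of the internal time covariate


def _fixed_formula(df: pd.DataFrame, with_time: bool = True) -> str:
    """Fixed-effects formula; the gender factor is dropped if only one
    level is present (it would be inestimable)."""
    terms = ["time_c"] if with_time else []
    terms += ["age"]
    if df["gender"].nunique() > 1:
        terms.append("C(gender, Treatment('female'))")
    terms.append("baseline")
    return "score ~ " + " + ".join(terms)


def _accept(fit) -> bool:
    return bool(np.isfinite(fit.llf) and np.all(np.isfinite(fit.fe_params))
                and np.all(np.isfinite(fit.bse_fe)))


def _fit_mixed(model):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for kwargs in ({}, {"method": "powell"}, {"method": "lbfgs"}):
            try:
                fit = model.fit(reml=False, maxiter=200, **kwargs)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if _accept(fit):
                return fit
    raise RuntimeError("mixed-model fit failed")


def _fit_crossed(formula: str, df: pd.DataFrame, random_slope: bool):
    vc = {
        "participant": "0 + C(participant_id)",
        "timepoint": "0 + C(time_since_dbs)",
    }
    if random_slope:
        vc["participant_slope"] = "0 + C(participant_id):time_c"
    model = smf.mixedlm(formula, df, groups=np.ones(len(df)),
                        vc_formula=vc, re_formula="0")
    return _fit_mixed(model)


def _fit_simple(formula: str, df: pd.DataFrame):
    model = smf.mixedlm(formula, df, groups=df["participant_id"])
    return _fit_mixed(model)


def longitudinal_mixed_model(visits: pd.DataFrame, participants: pd.DataFrame,
                             outcome: str = "ybocs",
                             random_slope: bool = False) -> MixedModelResult:
    """Linear mixed model of score over time since DBS.

    Fixed effects: time since DBS (the coefficient of interest, points per
    day; negative = improvement), age, gender (reference female) and
    baseline score.  Random effects: crossed random intercepts for
    participant and for timepoint; ``random_slope=True`` adds a
    per-participant random slope variance component.  A likelihood-ratio
    test against the null model omitting time is reported (ML fits).

    On non-convergence the model falls back to a single random intercept
    per participant, flagged in ``fallback``.
    """
    df = _prepare_longitudinal(visits, participants, outcome)
    fixed = _fixed_formula(df, with_time=True)
    null_f = _fixed_formula(df, with_time=False)
    fallback = None
    try:
        full = _fit_crossed(fixed, df, random_slope)
        null = _fit_crossed(null_f, df, random_slope)
        converged = bool(full.converged and null.converged)
    except Exception:
        fallback = "random intercept for participant only (crossed fit failed)"
        full = _fit_simple(fixed, df)
        null = _fit_simple(null_f, df)
        converged = bool(full.converged and null.converged)

    fe = full.fe_params
    terms, est, se, tv, pv = [], [], [], [], []
    rename = {
        "Intercept": "intercept",
        "C(gender, Treatment('female'))[T.male]": "gender_male",
        "time_c": "time_since_dbs",
    }
    for name in fe.index:
        # the internally scaled time covariate is reported in points per day
        scale = _TIME_SCALE if name == "time_c" else 1.0
        terms.append(rename.get(name, name))
        est.append(float(fe[name]) / scale)
        se.append(float(full.bse_fe[name]) / scale)
        tv.append(float(fe[name] / full.bse_fe[name]) if full.bse_fe[name] > 0 else np.nan)
        pv.append(float(full.pvalues[name]) if name in full.pvalues.index else np.nan)
    coef = pd.DataFrame({"term": terms, "estimate": est, "se": se,
                         "tvalue": tv, "pvalue": pv})

    chi2 = max(0.0, 2.0 * (float(full.llf) - float(null.llf)))
    lrt_p = float(stats.chi2.sf(chi2, 1))
    return MixedModelResult(
        coefficients=coef,
        lrt_chi2=chi2, lrt_df=1, lrt_p=lrt_p,
        converged=converged, fallback=fallback,
        n_obs=len(df), n_participants=df["participant_id"].nunique(),
        notes="gender reference level: female; time in days since implantation",
    )


# ---------------------------------------------------------------------------
# CBT additive effect and normality
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedResult:
    mean_diff: float
    sd_diff: float
    t: float
    p: float
    ci95: tuple[float, float]
    n: int


def cbt_effect(visits: pd.DataFrame, outcome: str = "ybocs") -> PairedResult:
    """Paired comparison of the pre-CBT plateau with the post-CBT score.

    Pre = last open-phase score, post = last cbt/post-cbt score, per
    participant; difference pre - post so positive means additional
    improvement from CBT.  Participants whose post-CBT scores are LOCF
    carry-forwards (withdrawn before CBT) are excluded.
    """
    pre, post = [], []
    for pid, sub in visits.groupby("participant_id"):
        sub = sub.sort_values("visit_day")
        p_open = sub.loc[sub["phase"] == "open", outcome]
        p_cbt = sub.loc[sub["phase"].isin(["cbt", "post-cbt"])]
        if p_open.empty or p_cbt.empty:
            continue
        if "locf" in sub.columns and bool(p_cbt["locf"].iloc[-1]):
            continue
        pre.append(float(p_open.iloc[-1]))
        post.append(float(p_cbt[outcome].iloc[-1]))
    pre, post = np.asarray(pre), np.asarray(post)
    if pre.size < 2:
        raise OutcomeError("need at least 2 complete pre/post CBT pairs")
    d = pre - post
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        t = 0.0 if mean == 0 else np.inf * np.sign(mean)
        p = 1.0 if mean == 0 else 0.0
        return PairedResult(mean, 0.0, t, p, (mean, mean), d.size)
    tt = stats.ttest_rel(pre, post)
    sem = sd / np.sqrt(d.size)
    tcrit = stats.t.ppf(0.975, d.size - 1)
    return PairedResult(mean, sd, float(tt.statistic), float(tt.pvalue),
                        (mean - tcrit * sem, mean + tcrit * sem), int(d.size))


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p for 3 <= n <= 5000 non-constant data."""
    vals = np.asarray(values, dtype=float)
    if not (3 <= vals.size <= 5000):
        raise OutcomeError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(vals) == 0:
        raise OutcomeError("Shapiro-Wilk undefined for constant data")
    w, p = stats.shapiro(vals)
    return float(w), float(p)


# ---------------------------------------------------------------------------
# LOCF pre-processing
# ---------------------------------------------------------------------------

def apply_locf(visits: pd.DataFrame, participants: pd.DataFrame) -> pd.DataFrame:
    """Carry each withdrawn participant's last observed scores forward.

    Uses ``participants.withdrawn_at``; visits after that day get the last
    pre-withdrawal YBOCS/MADRS and ``locf=True`` in the audit column.
    """
    out = visits.copy()
    if "locf" not in out.columns:
        out["locf"] = False
    for _, row in participants.iterrows():
        wday = row.get("withdrawn_at", np.nan)
        if pd.isna(wday):
            continue
        pid = row["participant_id"]
        sel = out["participant_id"] == pid
        sub = out.loc[sel].sort_values("visit_day")
        observed = sub[sub["visit_day"] <= wday]
        if observed.empty:
            raise OutcomeError(f"participant {pid} withdrew before any visit")
        last = observed.iloc[-1]
        late = sel & (out["visit_day"] > wday)
        out.loc[late, ["ybocs", "madrs"]] = (last["ybocs"], last["madrs"])
        out.loc[late, "locf"] = True
    return out
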