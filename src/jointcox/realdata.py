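"""Transition-to-psychosis study stage.

The applied dataset this stage targets is a cohort of ultra-high-risk
(UHR) patients followed for transition to psychosis, stored as
period-based records: one row per assessment period with the subject id,
family history of mental illness (yes/no, the group covariate), the period
start and end day, the transition status (yes only on a subject's final
period) and the Hamilton Depression Rating Scale (HAMD) total score
(0-96), the time-dependent predictor.  The score on a period is treated as
measured at the period start, the first period's start is the time origin,
and follow-up may exceed one year.

Because that file is study data distributed separately, the module also
provides :func:`synthetic_real_table`, a generator of a synthetic stand-in
table with the same schema (47 subjects, 29 with family history, HAMD-like
scores) so the plumbing can be exercised and tested without it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cox import build_baseline_table, build_locf_table, fit_cox
from .joint import JointSpec, fit_joint

__all__ = [
    "read_real_data",
    "describe",
    "analyze_real",
    "to_analysis_frames",
    "synthetic_real_table",
]

CANONICAL = ["subject_id", "family_history", "start_day", "end_day",
             "transition", "hamd"]

_SYNONYMS = {
    "subject_id": {"subject_id", "subject", "id", "subject_number", "subjectno"},
    "family_history": {"family_history", "familyhistory", "fh",
                       "family_history_of_mental_illness"},
    "start_day": {"start_day", "start", "startday", "period_start"},
    "end_day": {"end_day", "end", "endday", "stop", "period_end"},
    "transition": {"transition", "transition_status", "status", "event",
                   "transition_to_psychosis_status"},
    "hamd": {"hamd", "depression_score", "depression", "score",
             "depression_severity_score", "hamd_total"},
}


def _normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    mapping = {}
    for col in df.columns:
        key = col.strip().lower().replace(" ", "_").replace("-", "_")
        for canon, names in _SYNONYMS.items():
            if key in names:
                mapping[col] = canon
                break
    df = df.rename(columns=mapping)
    missing = [c for c in CANONICAL if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    return df[CANONICAL]


def _coerce_yesno(col: pd.Series) -> pd.Series:
    if col.dtype == object:
        mapped = col.str.strip().str.lower().map({"yes": 1, "no": 0, "1": 1, "0": 0})
        if mapped.isna().any():
            bad = col.index[mapped.isna()].tolist()
            raise ValueError(f"unparseable yes/no values at rows {bad[:5]}")
        return mapped.astype(int)
    return col.astype(int)


def validate_real_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the period-record invariants; raise listing offending rows."""
    errors = []
    bad = df.index[df["start_day"] >= df["end_day"]].tolist()
    if bad:
        errors.append(f"start_day >= end_day at rows {bad}")
    bad = df.index[(df["hamd"] < 0) | (df["hamd"] > 96)].tolist()
    if bad:
        errors.append(f"HAMD outside [0, 96] at rows {bad}")
    for sid, g in df.groupby("subject_id"):
        g = g.sort_values("start_day")
        s, e = g["start_day"].to_numpy(), g["end_day"].to_numpy()
        if np.any(s[1:] != e[:-1]):
            errors.append(f"subject {sid}: periods not contiguous")
        if g["transition"].to_numpy()[:-1].any():
            errors.append(f"subject {sid}: transition before final period")
        if g["family_history"].nunique() > 1:
            errors.append(f"subject {sid}: family history not constant")
    if errors:
        raise ValueError("; ".join(errors))
    return df


def read_real_data(path) -> pd.DataFrame:
    """Read and validate a period-record CSV (column names are flexible)."""
    df = _normalize_columns(pd.read_csv(path))
    df["family_history"] = _coerce_yesno(df["family_history"])
    df["transition"] = _coerce_yesno(df["transition"])
    for c in ("start_day", "end_day", "hamd"):
        df[c] = pd.to_numeric(df[c])
    return validate_real_table(df.reset_index(drop=True))


def describe(df: pd.DataFrame) -> dict:
    """Descriptive statistics of the cohort and outcome."""
    df = df.copy()
    for c in ("family_history", "transition"):
        df[c] = _coerce_yesno(df[c])
    per = df.sort_values(["subject_id", "start_day"]).groupby("subject_id")
    last = per.tail(1)
    origin = per["start_day"].first()
    follow = last.set_index("subject_id")["end_day"] - origin
    trans = last.set_index("subject_id")["transition"].astype(bool)
    t_times = follow[trans]
    c_times = follow[~trans]
    return {
        "n_subjects": int(per.ngroups),
        "n_family_history": int(last["family_history"].sum()),
        "n_transitions": int(trans.sum()),
        "hamd_mean": float(df["hamd"].mean()),
        "hamd_min": float(df["hamd"].min()),
        "hamd_max": float(df["hamd"].max()),
        "transition_time_mean": float(t_times.mean()) if len(t_times) else np.nan,
        "transition_time_median": float(t_times.median()) if len(t_times) else np.nan,
        "transition_time_range": (float(t_times.min()), float(t_times.max()))
        if len(t_times) else (np.nan, np.nan),
        "censoring_time_mean": float(c_times.mean()) if len(c_times) else np.nan,
        "censoring_time_range": (float(c_times.min()), float(c_times.max()))
        if len(c_times) else (np.nan, np.nan),
    }


def to_analysis_frames(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convert period records into the long + survival frame pair.

    The HAMD score of a period is a visit at the period's start day; days
    are shifted so each subject's first period starts at 0.
    """
    df = df.copy()
    for c in ("family_history", "transition"):
        df[c] = _coerce_yesno(df[c])
    df = df.sort_values(["subject_id", "start_day"])
    long_rows, surv_rows = [], []
    for sid, g in df.groupby("subject_id"):
        origin = g["start_day"].iloc[0]
        days = g["start_day"].to_numpy(dtype=float) - origin
        for d, v in zip(days, g["hamd"].to_numpy(dtype=float)):
            long_rows.append((sid, d, v))
        surv_rows.append((
            sid,
            int(g["family_history"].iloc[0]),
            float(g["end_day"].iloc[-1] - origin),
            int(g["transition"].iloc[-1]),
        ))
    long_df = pd.DataFrame(long_rows, columns=["subject_id", "day", "value"])
    surv_df = pd.DataFrame(surv_rows, columns=["subject_id", "group", "time", "status"])
    return long_df, surv_df


def _wald_p(est: float, se: float) -> float:
    return float(2.0 * sps.norm.sf(abs(est) / se))


def analyze_real(df: pd.DataFrame,
                 methods=("cox_baseline", "cox_locf", "joint_weibull", "joint_pc"),
                 joint_spec_overrides: dict | None = None) -> pd.DataFrame:
    """Fit every requested method; one row per method with (est, se, p).

    ``lambda1`` is the effect of the depression score on the transition
    hazard and ``tau`` the family-history effect.  A method that fails to
    converge yields an NA row.
    """
    long_df, surv_df = to_analysis_frames(df)
    overrides = joint_spec_overrides or {}
    rows = []
    for method in methods:
        row = {"method": method, "est_lambda1": np.nan, "se_lambda1": np.nan,
               "p_lambda1": np.nan, "est_tau": np.nan, "se_tau": np.nan,
               "p_tau": np.nan}
        try:
            if method == "cox_baseline":
                fit = fit_cox(build_baseline_table(long_df=long_df, surv_df=surv_df))
            elif method == "cox_locf":
                fit = fit_cox(build_locf_table(long_df=long_df, surv_df=surv_df))
            elif method in ("joint_weibull", "joint_pc"):
                baseline = ("weibull" if method == "joint_weibull"
                            else "piecewise_constant")
                fit = fit_joint(long_df=long_df, surv_df=surv_df,
                                spec=JointSpec(baseline=baseline, **overrides))
            else:
                raise ValueError(f"unknown method {method!r}")
            if fit.converged:
                if method.startswith("cox"):
                    l1, tau = fit.coef
                    se1, se2 = fit.se
                else:
                    l1, tau = fit.alpha, fit.gamma
                    se1, se2 = fit.se_alpha, fit.se_gamma
                row.update(est_lambda1=l1, se_lambda1=se1, p_lambda1=_wald_p(l1, se1),
                           est_tau=tau, se_tau=se2, p_tau=_wald_p(tau, se2))
        except ValueError:
            raise
        except Exception:
            pass
        rows.append(row)
    return pd.DataFrame(rows)


def synthetic_real_table(seed: int = 20, n_subjects: int = 47,
                         n_family_history: int = 29) -> pd.DataFrame:
    """SYNTHETIC stand-in for the transition-to-psychosis period table.

    Not the study data: a simulated cohort with the same schema and broadly
    similar magnitudes (HAMD-like integer scores, ~monthly periods, roughly
    half the cohort transitioning within 1-2 years), generated from the
    package's own trajectory + log-linear hazard model so that analysis
    code paths can be exercised end to end.
    """
    rng = np.random.default_rng(seed)
    rows = []
    fh = np.zeros(n_subjects, dtype=int)
    fh[:n_family_history] = 1
    rng.shuffle(fh)
    for sid in range(1, n_subjects + 1):
        b0 = rng.normal(0.0, 6.0)
        b1 = rng.normal(0.0, 0.01)
        score = lambda t: 17.0 + 0.005 * t + b0 + b1 * t
        # period grid: monthly with jitter, up to ~24 months
        days = [0.0]
        while days[-1] < 720:
            days.append(days[-1] + 30 + rng.integers(-7, 8))
        days = np.array(days)
        # event via daily log-linear hazard in the latent score
        horizon = int(days[-1])
        h = np.exp(-7.9 + 0.08 * score(np.arange(horizon)) + 0.5 * fh[sid - 1])
        e = rng.standard_exponential(horizon)
        hit = e <= h
        T = np.inf
        if hit.any():
            first = int(np.argmax(hit))
            T = first + e[first] / h[first]
        C = float(rng.uniform(330, 720))
        time, status = (T, 1) if T <= C else (C, 0)
        keep = days[days < time]
        edges = np.append(keep, time)
        for j in range(len(keep)):
            rows.append((
                sid, "yes" if fh[sid - 1] else "no",
                float(edges[j]), float(edges[j + 1]),
                "yes" if (status == 1 and j == len(keep) - 1) else "no",
                int(np.clip(round(score(edges[j]) + rng.normal(0, 4.0)), 0, 96)),
            ))
    return pd.DataFrame(rows, columns=[
        "subject_id", "family_history", "start_day", "end_day",
        "transition", "hamd"])
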