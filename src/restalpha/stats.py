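"""Inferential group statistics for the alpha features.

Implements the 2 (group, between) x 2 (hemisphere, within) x 2 (region,
within) mixed-design ANOVA with partial eta squared and noncentral-F 90%
confidence intervals, directional and paired t-tests with Cohen's d and
noncentral-t 90% CIs, and the Dunn-Sidak familywise-corrected per-test
threshold.

The mixed ANOVA uses the classical balanced sums-of-squares decomposition
with separate error strata: subjects-within-group for the between effect
and the subject x within-factor interaction (pooled within groups) for
each within effect.  Both within factors have two levels, so sphericity
holds trivially and no correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sst

__all__ = [
    "AnovaEffect",
    "TTestResult",
    "mixed_anova_222",
    "t_test",
    "dunn_sidak_threshold",
    "cohens_d_from_t",
    "partial_eta_sq",
    "connectivity_group_tests",
    "alpha_feature_anova_frame",
]

GROUPS = ("HSG", "LSG")


@dataclass
class AnovaEffect:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float
    eta_ci_90: tuple[float, float]


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    tail: str           # "one" or "two"
    design: str         # "paired" or "independent"
    cohens_d: float
    d_ci_90: tuple[float, float]


def dunn_sidak_threshold(alpha: float = 0.05, k: int = 1) -> float:
    """Familywise-corrected per-comparison threshold 1 - (1-alpha)^(1/k)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return 1.0 - (1.0 - alpha) ** (1.0 / k)


def cohens_d_from_t(t: float, n1: int, n2: int | None = None) -> float:
    """Effect size from a t statistic: paired d = t/sqrt(n), independent
    d = t*sqrt(1/n1 + 1/n2)."""
    if n2 is None:
        return t / np.sqrt(n1)
    return t * np.sqrt(1.0 / n1 + 1.0 / n2)


def partial_eta_sq(F: float, df_num: int, df_den: int) -> float:
    """Partial eta squared from F: F*df_num / (F*df_num + df_den)."""
    return F * df_num / (F * df_num + df_den)


def _ncp_interval(stat: float, cdf, lo_hint: float, hi_hint: float,
                  level: float = 0.90) -> tuple[float, float]:
    """Noncentrality-parameter pivot interval by inverting a cdf in ncp."""
    tail = (1.0 - level) / 2.0

    def safe_cdf(ncp: float) -> float:
        v = cdf(stat, ncp)
        if np.isnan(v):  # extreme-ncp underflow; cdf is decreasing in ncp
            return 1.0 if ncp < stat else 0.0
        return float(v)

    def solve(target: float, lo: float, hi: float) -> float:
        f = lambda ncp: safe_cdf(ncp) - target
        try:
            if f(lo) * f(hi) > 0:
                return lo if target > 0.5 else hi
            return optimize.brentq(f, lo, hi, xtol=1e-10)
        except ValueError:
            return np.nan

    lower = solve(1.0 - tail, lo_hint, hi_hint)
    upper = solve(tail, lo_hint, hi_hint)
    return lower, upper


def _d_ci_90(t: float, df: int, n1: int, n2: int | None) -> tuple[float, float]:
    """90% CI for Cohen's d via the noncentral-t pivot."""
    scale = 1.0 / np.sqrt(n1) if n2 is None else np.sqrt(1.0 / n1 + 1.0 / n2)
    cdf = lambda stat, ncp: sst.nct.cdf(stat, df, ncp)
    span = max(abs(t), 1.0) * 10 + 10
    lo, hi = _ncp_interval(t, cdf, -span, span)
    return (lo * scale, hi * scale)


def _eta_ci_90(F: float, df_num: int, df_den: int) -> tuple[float, float]:
    """90% CI for partial eta squared via the noncentral-F pivot."""
    cdf = lambda stat, ncp: sst.ncf.cdf(stat, df_num, df_den, ncp)
    span = max(F * df_num, 1.0) * 20 + 50
    lo, hi = _ncp_interval(F, cdf, 0.0, span)

    def to_eta(ncp: float) -> float:
        if np.isnan(ncp):
            return np.nan
        return max(ncp, 0.0) / (max(ncp, 0.0) + df_num + df_den + 1)

    return (to_eta(lo), to_eta(hi))


def t_test(
    a: np.ndarray,
    b: np.ndarray,
    design: str = "independent",
    tail: str = "two",
    direction: str | None = None,
) -> TTestResult:
    """Pooled-variance independent or paired t-test with Cohen's d.

    One-tailed tests require an explicit ``direction`` (``"greater"`` or
    ``"less"``, referring to sample ``a`` vs ``b``): the hypothesized
    direction is part of the analysis plan, never inferred from the data.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    if tail == "one":
        if direction not in ("greater", "less"):
            raise ValueError("one-tailed tests require direction='greater' or 'less'")
        alternative = direction
    else:
        alternative = "two-sided"
    if design == "paired":
        if a.size != b.size:
            raise ValueError("paired design requires equal lengths")
        if np.var(a - b) == 0 and np.all(a == b):
            t_stat, df = 0.0, a.size - 1
            p = 1.0 if tail == "two" else 0.5
        else:
            res = sst.ttest_rel(a, b, alternative=alternative)
            t_stat, p, df = float(res.statistic), float(res.pvalue), a.size - 1
        d = cohens_d_from_t(t_stat, a.size)
        ci = _d_ci_90(t_stat, df, a.size, None)
    elif design == "independent":
        if a.size < 2 or b.size < 2:
            raise ValueError("independent design requires n >= 2 per sample")
        if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
            t_stat, df = 0.0, a.size + b.size - 2
            p = 1.0 if tail == "two" else 0.5
        else:
            res = sst.ttest_ind(a, b, equal_var=True, alternative=alternative)
            t_stat, p, df = float(res.statistic), float(res.pvalue), a.size + b.size - 2
        d = cohens_d_from_t(t_stat, a.size, b.size)
        ci = _d_ci_90(t_stat, df, a.size, b.size)
    else:
        raise ValueError("design must be 'paired' or 'independent'")
    return TTestResult(
        t=t_stat, df=df, p=p, tail=tail, design=design, cohens_d=float(d), d_ci_90=ci
    )


def _cell_array(frame: pd.DataFrame, dv: str) -> tuple[np.ndarray, np.ndarray, list]:
    """Reshape the long feature frame to (subjects x hemi x region)."""
    required = {"subject_id", "group", "hemisphere", "region", dv}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"feature frame missing columns {sorted(missing)}")
    hemis, regions = ("L", "R"), ("frontal", "parieto-occipital")
    subjects = list(dict.fromkeys(frame["subject_id"]))
    groups = []
    Y = np.full((len(subjects), 2, 2), np.nan)
    for si, s in enumerate(subjects):
        sub = frame[frame["subject_id"] == s]
        g = set(sub["group"])
        if len(g) != 1:
            raise ValueError(f"subject {s} has multiple group labels")
        groups.append(g.pop())
        for hi, h in enumerate(hemis):
            for ri, r in enumerate(regions):
                sel = sub[(sub["hemisphere"] == h) & (sub["region"] == r)][dv]
                if len(sel) != 1:
                    raise ValueError(
                        f"subject {s} does not have exactly one value for "
                        f"hemisphere={h}, region={r} (incomplete design)"
                    )
                Y[si, hi, ri] = float(sel.iloc[0])
    groups = np.asarray(groups)
    counts = pd.Series(groups).value_counts()
    if len(counts) != 2 or counts.iloc[0] != counts.iloc[1]:
        raise ValueError(f"design must be balanced with two groups; got {dict(counts)}")
    return Y, groups, subjects


def mixed_anova_222(frame: pd.DataFrame, dv: str = "value") -> list[AnovaEffect]:
    """Balanced 2x2x2 mixed ANOVA (group between; hemisphere, region within).

    Returns the seven effects: GROUP, HEMI, GROUP:HEMI, REGION,
    GROUP:REGION, HEMI:REGION, GROUP:HEMI:REGION, each with F, dfs, p,
    partial eta squared and its 90% CI.
    """
    Y, groups, _ = _cell_array(frame, dv)
    glabels = sorted(set(groups))
    gidx = np.array([glabels.index(g) for g in groups])
    N = Y.shape[0]
    n = N // 2
    grand = Y.mean()

    subj_mean = Y.mean(axis=(1, 2))            # per subject
    grp_mean = np.array([subj_mean[gidx == i].mean() for i in range(2)])
    h_mean = Y.mean(axis=(0, 2))
    r_mean = Y.mean(axis=(0, 1))
    gh_mean = np.array([[Y[gidx == i, hi, :].mean() for hi in range(2)] for i in range(2)])
    gr_mean = np.array([[Y[gidx == i, :, ri].mean() for ri in range(2)] for i in range(2)])
    hr_mean = Y.mean(axis=0)
    ghr_mean = np.array([Y[gidx == i].mean(axis=0) for i in range(2)])
    sh_mean = Y.mean(axis=2)                   # subject x hemi
    sr_mean = Y.mean(axis=1)                   # subject x region

    ss_g = 4 * n * np.sum((grp_mean - grand) ** 2)
    ss_s = 4 * np.sum((subj_mean - grp_mean[gidx]) ** 2)
    ss_h = 2 * N * np.sum((h_mean - grand) ** 2)
    ss_gh = 2 * n * np.sum(
        (gh_mean - grp_mean[:, None] - h_mean[None, :] + grand) ** 2
    )
    ss_hs = 2 * np.sum(
        (sh_mean - subj_mean[:, None] - gh_mean[gidx] + grp_mean[gidx, None]) ** 2
    )
    ss_r = 2 * N * np.sum((r_mean - grand) ** 2)
    ss_gr = 2 * n * np.sum(
        (gr_mean - grp_mean[:, None] - r_mean[None, :] + grand) ** 2
    )
    ss_rs = 2 * np.sum(
        (sr_mean - subj_mean[:, None] - gr_mean[gidx] + grp_mean[gidx, None]) ** 2
    )
    ss_hr = N * np.sum(
        (hr_mean - h_mean[:, None] - r_mean[None, :] + grand) ** 2
    )
    ss_ghr = n * np.sum(
        (
            ghr_mean
            - gh_mean[:, :, None]
            - gr_mean[:, None, :]
            - hr_mean[None, :, :]
            + grp_mean[:, None, None]
            + h_mean[None, :, None]
            + r_mean[None, None, :]
            - grand
        )
        ** 2
    )
    # three-way subject interaction residual
    expected = (
        sh_mean[:, :, None]
        + sr_mean[:, None, :]
        + ghr_mean[gidx]
        - subj_mean[:, None, None]
        - gh_mean[gidx][:, :, None]
        - gr_mean[gidx][:, None, :]
        + grp_mean[gidx][:, None, None]
    )
    ss_hrs = np.sum((Y - expected) ** 2)

    df_err = N - 2
    table = [
        ("GROUP", ss_g, ss_s),
        ("HEMI", ss_h, ss_hs),
        ("GROUP:HEMI", ss_gh, ss_hs),
        ("REGION", ss_r, ss_rs),
        ("GROUP:REGION", ss_gr, ss_rs),
        ("HEMI:REGION", ss_hr, ss_hrs),
        ("GROUP:HEMI:REGION", ss_ghr, ss_hrs),
    ]
    ss_total = float(np.sum((Y - grand) ** 2))
    tiny = 1e-12 * max(ss_total, 1e-300)  # absorbs round-off in exact-zero designs
    effects = []
    for name, ss_eff, ss_err in table:
        ms_err = ss_err / df_err
        if ss_eff <= tiny:
            F = 0.0
        elif ss_err <= tiny:
            F = np.inf
        else:
            F = ss_eff / ms_err
        p = float(sst.f.sf(F, 1, df_err))
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        effects.append(
            AnovaEffect(
                effect=name,
                F=float(F),
                df_num=1,
                df_den=df_err,
                p=p,
                partial_eta_sq=float(eta),
                eta_ci_90=_eta_ci_90(F, 1, df_err),
            )
        )
    return effects


def alpha_feature_anova_frame(
    features: pd.DataFrame, measure: str
) -> pd.DataFrame:
    """Long-format ANOVA frame from the wide per-subject feature table.

    ``measure`` is ``"iaf"`` or ``"amp"``; subjects with any missing cell
    (e.g. no detectable alpha peak) are excluded listwise.
    """
    cols = {
        ("L", "frontal"): f"{measure}_frontal_L",
        ("R", "frontal"): f"{measure}_frontal_R",
        ("L", "parieto-occipital"): f"{measure}_posterior_L",
        ("R", "parieto-occipital"): f"{measure}_posterior_R",
    }
    rows = []
    for _, rec in features.iterrows():
        vals = {k: rec[c] for k, c in cols.items()}
        if any(pd.isna(v) for v in vals.values()):
            continue
        for (h, r), v in vals.items():
            rows.append(
                {
                    "subject_id": rec["subject_id"],
                    "group": rec["group"],
                    "hemisphere": h,
                    "region": r,
                    "value": v,
                }
            )
    return pd.DataFrame(rows)


def connectivity_group_tests(features: pd.DataFrame) -> pd.DataFrame:
    """Planned two-tailed HSG-vs-LSG comparisons of the connectivity features.

    One row per feature (wpli/tli x intra_L, intra_R, inter) with the
    Dunn-Sidak threshold for three comparisons per feature family.
    """
    out = []
    thr = dunn_sidak_threshold(0.05, 3)
    for fam in ("wpli", "tli"):
        for name in ("intra_L", "intra_R", "inter"):
            col = f"{fam}_{name}"
            a = features.loc[features["group"] == "HSG", col].dropna().to_numpy()
            b = features.loc[features["group"] == "LSG", col].dropna().to_numpy()
            res = t_test(a, b, design="independent", tail="two")
            out.append(
                {
                    "feature": col,
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "cohens_d": res.cohens_d,
                    "d_ci_lo": res.d_ci_90[0],
                    "d_ci_hi": res.d_ci_90[1],
                    "corrected_threshold": thr,
                    "significant": res.p < thr,
                }
            )
    return pd.DataFrame(out)
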