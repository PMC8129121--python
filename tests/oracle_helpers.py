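"""Independent brute-force oracles used by the test suite.

These deliberately take a different computational route from the package:
the mixed-ANOVA oracle reduces each within-subject effect to a per-subject
contrast score and runs ordinary least-squares F-tests on those scores,
instead of the sums-of-squares decomposition the package uses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _ols_f(y: np.ndarray, X_full: np.ndarray, X_null: np.ndarray) -> tuple[float, int, int]:
    """F statistic for comparing nested linear models via residual sums."""

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r), X.shape[1]

    rss_full, p_full = rss(X_full)
    rss_null, p_null = rss(X_null)
    df_num = p_full - p_null
    df_den = len(y) - p_full
    F = ((rss_null - rss_full) / df_num) / (rss_full / df_den)
    return F, df_num, df_den


def mixed_anova_oracle(frame: pd.DataFrame, dv: str = "value") -> dict[str, float]:
    """F values of the 2x2x2 mixed design via contrast scores + OLS.

    Between effect: one-way ANOVA on per-subject means.  Each within
    effect w: per-subject contrast score z_s = sum over cells of
    c_w(cell) * y_s(cell); the main effect of w is the intercept F of
    z ~ 1 + group, and the group x w interaction is the group F.
    """
    hemis, regions = ("L", "R"), ("frontal", "parieto-occipital")
    subjects = list(dict.fromkeys(frame["subject_id"]))
    Y = np.zeros((len(subjects), 2, 2))
    g = []
    for si, s in enumerate(subjects):
        sub = frame[frame["subject_id"] == s]
        g.append(sub["group"].iloc[0])
        for hi, h in enumerate(hemis):
            for ri, r in enumerate(regions):
                Y[si, hi, ri] = float(
                    sub[(sub["hemisphere"] == h) & (sub["region"] == r)][dv].iloc[0]
                )
    glabels = sorted(set(g))
    gsign = np.array([1.0 if x == glabels[0] else -1.0 for x in g])
    ones = np.ones(len(subjects))

    out: dict[str, float] = {}
    # between effect on subject means
    m = Y.mean(axis=(1, 2))
    F, _, _ = _ols_f(m, np.column_stack([ones, gsign]), ones[:, None])
    out["GROUP"] = F

    contrasts = {
        "HEMI": np.array([[1.0, 1.0], [-1.0, -1.0]]) / 2.0,
        "REGION": np.array([[1.0, -1.0], [1.0, -1.0]]) / 2.0,
        "HEMI:REGION": np.array([[1.0, -1.0], [-1.0, 1.0]]) / 2.0,
    }
    for name, c in contrasts.items():
        z = (Y * c[None]).sum(axis=(1, 2))
        X_full = np.column_stack([ones, gsign])
        # intercept F: compare against the model without the intercept
        F_w, _, _ = _ols_f(z, X_full, gsign[:, None])
        F_gw, _, _ = _ols_f(z, X_full, ones[:, None])
        out[name] = F_w
        out[f"GROUP:{name}" if ":" not in name else "GROUP:HEMI:REGION"] = F_gw
    return out


def permutation_p_independent(
    a: np.ndarray, b: np.ndarray, n_perm: int = 20000, seed: int = 0
) -> float:
    """Two-sided permutation p-value for a difference in means."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    obs = abs(a.mean() - b.mean())
    n = len(a)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:n].mean() - perm[n:].mean()) >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)
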