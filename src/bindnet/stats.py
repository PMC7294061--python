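"""Repeated-measures statistics for the 2x2 binding design.

The dependent measures (accuracy, RT, P3 / C-cluster amplitude, small-world
omega) are analyzed in a fully within-subject two-way ANOVA with feature
overlap and response relation as factors.  Each effect is tested against its
own subject-by-effect interaction error term; effect size is partial eta
squared, SS_effect / (SS_effect + SS_error).  With 2-level factors no
sphericity correction is needed.  Post-hoc paired contrasts are Bonferroni
corrected.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "rm_anova_two_way",
    "rm_anova_2x2",
    "posthoc_paired",
    "partial_eta_sq_ci",
    "bic_bayes_factor",
    "binding_effect_report",
    "table_from_long",
]


def table_from_long(df: pd.DataFrame, value: str, subject: str = "subject",
                    a: str = "overlap", b: str = "response") -> np.ndarray:
    """Pivot a long table into the subjects x levelsA x levelsB array the
    ANOVA consumes; raises if any subject/cell combination is missing or
    duplicated."""

    piv = df.pivot_table(index=subject, columns=[a, b], values=value,
                         aggfunc="mean")
    if piv.isna().any().any():
        raise ValueError("unbalanced table: missing subject x cell values")
    counts = df.groupby([subject, a, b]).size()
    if (counts != 1).any():
        raise ValueError("unbalanced table: duplicated subject x cell values")
    n_a = df[a].nunique()
    n_b = df[b].nunique()
    return piv.to_numpy().reshape(len(piv), n_a, n_b)


def _effect_row(name, ss_eff, df_eff, ss_err, df_err):
    if ss_eff <= 0:
        f, p, eta = 0.0, 1.0, 0.0
    elif ss_err <= 0:
        f, p, eta = np.inf, 0.0, 1.0
    else:
        f = (ss_eff / df_eff) / (ss_err / df_err)
        p = float(sps.f.sf(f, df_eff, df_err))
        eta = ss_eff / (ss_eff + ss_err)
    return {"effect": name, "ss_effect": ss_eff, "df_effect": df_eff,
            "ss_error": ss_err, "df_error": df_err, "F": f, "p": p,
            "partial_eta_sq": eta}


def rm_anova_two_way(data: np.ndarray) -> pd.DataFrame:
    """Balanced fully-within two-way ANOVA.

    Parameters
    ----------
    data
        subjects x levels_A x levels_B cell means.

    Returns
    -------
    DataFrame with one row per effect (A, B, AxB): sums of squares, degrees
    of freedom, F, p and partial eta squared.
    """

    x = np.asarray(data, float)
    if x.ndim != 3:
        raise ValueError("data must be subjects x levelsA x levelsB")
    n, a, b = x.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if np.any(~np.isfinite(x)):
        raise ValueError("data contains non-finite values")

    gm = x.mean()
    m_s = x.mean(axis=(1, 2))          # subject means
    m_a = x.mean(axis=(0, 2))          # A-level means
    m_b = x.mean(axis=(0, 1))
    m_sa = x.mean(axis=2)              # n x a
    m_sb = x.mean(axis=1)              # n x b
    m_ab = x.mean(axis=0)              # a x b

    ss_a = n * b * np.sum((m_a - gm) ** 2)
    ss_b = n * a * np.sum((m_b - gm) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2)
    resid = (x - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :] - gm)
    ss_abs = np.sum(resid ** 2)

    rows = [
        _effect_row("A", ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        _effect_row("B", ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        _effect_row("AxB", ss_ab, (a - 1) * (b - 1), ss_abs,
                    (a - 1) * (b - 1) * (n - 1)),
    ]
    return pd.DataFrame(rows)


def rm_anova_2x2(data: np.ndarray) -> pd.DataFrame:
    """Two-way RM ANOVA restricted to the 2x2 design (checks the shape)."""

    x = np.asarray(data, float)
    if x.ndim != 3 or x.shape[1:] != (2, 2):
        raise ValueError("expected subjects x 2 x 2 data")
    return rm_anova_two_way(x)


def posthoc_paired(
    cells: dict,
    comparisons: list[tuple[str, str]],
    correction: str = "bonferroni",
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Paired t-tests on named cell contrasts with Bonferroni correction.

    ``cells`` maps cell name -> per-subject values (equal length).  Cohen's d
    is the within-subject d_z (mean difference / SD of differences); when the
    difference has zero variance the test is degenerate and flagged.
    """

    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")
    k = len(comparisons)
    rows = []
    for name_a, name_b in comparisons:
        a = np.asarray(cells[name_a], float)
        b = np.asarray(cells[name_b], float)
        d = a - b
        n = d.size
        sd = d.std(ddof=1)
        degenerate = sd == 0
        if degenerate:
            if d.mean() == 0:
                t, p, dz = 0.0, 1.0, 0.0
            else:
                t = np.inf if d.mean() > 0 else -np.inf
                p, dz = 0.0, np.sign(d.mean()) * np.inf
        else:
            t, p = sps.ttest_rel(a, b, alternative=alternative)
            dz = d.mean() / sd
        p_corr = min(p * k, 1.0) if correction == "bonferroni" else p
        rows.append({"contrast": f"{name_a} - {name_b}", "t": float(t),
                     "df": n - 1, "p_corrected": float(p_corr),
                     "cohen_d": float(dz), "degenerate": degenerate})
    return pd.DataFrame(rows)


def partial_eta_sq_ci(f: float, df1: int, df2: int, conf: float = 0.90
                      ) -> tuple[float, float]:
    """Confidence interval for partial eta squared via noncentral-F
    inversion of the observed F statistic."""

    alpha = 1.0 - conf
    lam_max = max((f * df1 + df1 + df2) * 10.0, 100.0)

    def _sf(lam):
        if lam <= 0:
            return float(sps.f.sf(f, df1, df2))  # scipy ncf is unstable at 0
        return float(sps.ncf.sf(f, df1, df2, lam))

    def _bound(prob):
        # noncentrality lambda with P(F > f | lambda) == prob; the survival
        # function increases monotonically in lambda
        if _sf(0.0) >= prob:
            return 0.0
        try:
            return optimize.brentq(lambda lam: _sf(lam) - prob, 0.0, lam_max)
        except ValueError:
            return lam_max

    lam_lo = _bound(alpha / 2.0)
    lam_hi = _bound(1.0 - alpha / 2.0)
    to_eta = lambda lam: lam / (lam + df1 + df2 + 1.0)
    return (to_eta(lam_lo), to_eta(lam_hi))


def bic_bayes_factor(f: float, df1: int, df2: int, n: int) -> float:
    """BIC-approximation Bayes factor BF10 for one ANOVA effect.

    This is the Wagenmakers unit-information approximation from the model
    comparison BIC(H0) - BIC(H1); it is *not* equivalent to a default-prior
    JZS Bayes factor and is provided for rough orientation only.
    """

    r2 = (f * df1) / (f * df1 + df2)
    delta_bic = n * np.log(1.0 - r2) + df1 * np.log(n)
    return float(np.exp(-0.5 * delta_bic))


def binding_effect_report(measures: dict) -> pd.DataFrame:
    """Interaction summary across dependent measures.

    ``measures`` maps a measure name (accuracy, rt, p3, c_cluster, omega...)
    to a subjects x 2 x 2 array ordered [overlap 0, overlap 3] x
    [repeat, alternate]; ``None`` entries are skipped with a warning.  The
    report carries the interaction test plus the two simple-effect contrasts
    (overlap 0 vs 3 within each response relation, Bonferroni corrected).
    """

    rows = []
    for name, data in measures.items():
        if data is None:
            warnings.warn(f"measure {name!r} missing; omitted from report",
                          stacklevel=2)
            continue
        x = np.asarray(data, float)
        table = rm_anova_2x2(x)
        inter = table[table["effect"] == "AxB"].iloc[0]
        cells = {
            "o0_rep": x[:, 0, 0], "o3_rep": x[:, 1, 0],
            "o0_alt": x[:, 0, 1], "o3_alt": x[:, 1, 1],
        }
        ph = posthoc_paired(cells, [("o0_rep", "o3_rep"), ("o0_alt", "o3_alt")])
        rows.append({
            "measure": name,
            "interaction_F": inter["F"],
            "interaction_df1": inter["df_effect"],
            "interaction_df2": inter["df_error"],
            "interaction_p": inter["p"],
            "interaction_partial_eta_sq": inter["partial_eta_sq"],
            "repeat_o0_vs_o3_t": ph.loc[0, "t"],
            "repeat_o0_vs_o3_p": ph.loc[0, "p_corrected"],
            "alternate_o0_vs_o3_t": ph.loc[1, "t"],
            "alternate_o0_vs_o3_p": ph.loc[1, "p_corrected"],
        })
    return pd.DataFrame(rows)
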