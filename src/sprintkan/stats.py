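"""Repeated-measures inference for the cohort outcomes.

One-way within-subject ANOVA per outcome (velocity or band coherence)
across the three stimulation conditions, with Shapiro-Wilk normality
screening, Mauchly's sphericity test, Greenhouse-Geisser df correction,
Bonferroni-corrected paired post hocs and partial eta-squared effect
sizes. Effect sizes are also recoverable directly from a printed F
statistic via eta_p^2 = F*df1 / (F*df1 + df2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _st

logger = logging.getLogger(__name__)

ALPHA_LEVEL = 0.05


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    mean_diff: float
    t: float
    p_raw: float
    p_corrected: float


@dataclass
class AnovaResult:
    f_value: float
    df_effect: float
    df_error: float
    p_value: float
    gg_epsilon: float
    p_gg: float
    partial_eta_sq: float
    mauchly_w: float
    mauchly_p: float
    posthoc: list[PairwiseResult] = field(default_factory=list)

    @property
    def p_reported(self) -> float:
        """GG-corrected p when Mauchly indicates violation, else uncorrected."""
        return self.p_gg if self.mauchly_p < ALPHA_LEVEL else self.p_value


def _pivot(table: pd.DataFrame, dv: str, within: str, subject: str) -> pd.DataFrame:
    """Subject x condition matrix; errors on unbalanced data naming cells."""
    counts = table.groupby([subject, within], observed=True).size()
    bad = counts[counts != 1]
    wide = table.pivot_table(index=subject, columns=within, values=dv,
                             aggfunc="mean", observed=True)
    if len(bad) or wide.isna().any().any():
        missing = [f"{s}/{c}" for (s, c) in
                   wide.stack(future_stack=True)[wide.stack(future_stack=True).isna()].index]
        dup = [f"{s}/{c}" for (s, c) in bad.index]
        raise ValueError(f"unbalanced table; missing cells: {missing}; "
                         f"duplicated cells: {dup}")
    return wide


def shapiro_screen(table: pd.DataFrame, dv: str = "value",
                   within: str = "condition") -> dict[str, tuple[float, float]]:
    """Per-condition Shapiro-Wilk (W, p). Advisory: violations are logged,
    the pipeline proceeds."""
    out = {}
    for cond, grp in table.groupby(within, observed=True):
        x = grp[dv].to_numpy(dtype=float)
        if x.size < 3:
            raise ValueError(f"Shapiro-Wilk needs n >= 3 (condition {cond})")
        if np.ptp(x) == 0:
            raise ValueError(f"degenerate (constant) sample in condition {cond}")
        w, p = _st.shapiro(x)
        if p <= ALPHA_LEVEL:
            logger.warning("normality violated in condition %s (p=%.4f)", cond, p)
        out[str(cond)] = (float(w), float(p))
    return out


def gg_epsilon(wide: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the condition-score covariance."""
    S = np.cov(wide, rowvar=False, ddof=1)
    k = S.shape[0]
    J = np.eye(k) - np.ones((k, k)) / k
    A = J @ S @ J  # double-centred covariance
    tr = np.trace(A)
    denom = (k - 1) * np.sum(A * A)
    if denom <= 0:
        return 1.0
    eps = tr ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def mauchly(table: pd.DataFrame, dv: str = "value", within: str = "condition",
            subject: str = "participant") -> tuple[float, float]:
    """Mauchly's sphericity test (W, p) via pingouin."""
    import pingouin as pg  # deferred: heavy import
    res = pg.sphericity(data=table, dv=dv, within=within, subject=subject)
    return float(res.W), float(res.pval)


def rm_anova(table: pd.DataFrame, dv: str = "value", within: str = "condition",
             subject: str = "participant",
             posthoc: bool = True) -> AnovaResult:
    """Classical one-way repeated-measures ANOVA.

    Within-subject decomposition: SS_total = SS_subjects + SS_conditions +
    SS_error with df_effect = k-1 and df_error = (k-1)(n-1). Reports both
    the uncorrected and the Greenhouse-Geisser-corrected p; partial
    eta^2 = SS_effect / (SS_effect + SS_error).
    """
    wide = _pivot(table, dv, within, subject)
    Y = wide.to_numpy(dtype=float)
    n, k = Y.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if n < k:
        raise ValueError("need at least as many subjects as conditions")
    gm = Y.mean()
    ss_cond = n * float(((Y.mean(axis=0) - gm) ** 2).sum())
    ss_subj = k * float(((Y.mean(axis=1) - gm) ** 2).sum())
    ss_tot = float(((Y - gm) ** 2).sum())
    ss_err = max(ss_tot - ss_cond - ss_subj, 0.0)
    df_e, df_r = k - 1, (k - 1) * (n - 1)
    if ss_cond <= 1e-12 * max(ss_tot, 1e-300):  # no condition effect (roundoff)
        f = 0.0
        p = p_gg = 1.0
        eps = 1.0
        eta = 0.0
    else:
        ms_e = ss_cond / df_e
        ms_r = ss_err / df_r
        f = ms_e / ms_r if ms_r > 0 else np.inf
        p = float(_st.f.sf(f, df_e, df_r))
        eps = gg_epsilon(Y)
        p_gg = float(_st.f.sf(f, eps * df_e, eps * df_r))
        eta = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else 0.0
    try:
        w, wp = mauchly(table, dv, within, subject)
    except Exception:  # degenerate covariance
        w, wp = 1.0, 1.0
    ph = bonferroni_posthoc(table, dv, within, subject) if posthoc else []
    return AnovaResult(f_value=float(f), df_effect=float(df_e), df_error=float(df_r),
                       p_value=float(p), gg_epsilon=float(eps), p_gg=float(p_gg),
                       partial_eta_sq=float(eta), mauchly_w=w, mauchly_p=wp,
                       posthoc=ph)


def partial_eta_from_f(f: float, df_effect: float, df_error: float) -> float:
    """Back-compute partial eta^2 from an F statistic and its dfs."""
    if f < 0:
        raise ValueError("F must be >= 0")
    if df_effect < 1 or df_error < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(f * df_effect / (f * df_effect + df_error))


def bonferroni_posthoc(table: pd.DataFrame, dv: str = "value",
                       within: str = "condition",
                       subject: str = "participant") -> list[PairwiseResult]:
    """Paired t per condition pair; corrected p = min(1, raw * n_pairs)."""
    wide = _pivot(table, dv, within, subject)
    conds = list(wide.columns)
    pairs = list(combinations(conds, 2))
    out = []
    for a, b in pairs:
        xa, xb = wide[a].to_numpy(), wide[b].to_numpy()
        diff = xa - xb
        if np.ptp(diff) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = _st.ttest_rel(xa, xb)
        out.append(PairwiseResult(pair=(str(a), str(b)),
                                  mean_diff=float(diff.mean()),
                                  t=float(t), p_raw=float(p),
                                  p_corrected=float(min(1.0, p * len(pairs)))))
    return out
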