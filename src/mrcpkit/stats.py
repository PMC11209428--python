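"""Repeated-measures ANOVA layer.

One-way RM-ANOVA (session as the within factor) for the component
amplitudes, and two-way RM-ANOVA (session x classifier) for the
classification accuracies, with:

* Mauchly's test of sphericity (chi-square approximation),
* Greenhouse-Geisser (GG) degrees-of-freedom correction, applied when
  Mauchly's p < 0.05,
* partial eta-squared effect sizes, SS_effect / (SS_effect + SS_error),
* Bonferroni-corrected paired t-tests as the post hoc, run when the
  omnibus test is significant.

Input is the complete subjects x level grid (no missing cells).  The sums
of squares are computed from the classical decomposition directly, so that
SS_total = SS_subjects + SS_condition + SS_error holds to numerical
precision in the one-way case.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class AnovaResult:
    """One ANOVA effect: F, (possibly GG-adjusted, fractional) df, p,
    sphericity diagnostics, partial eta^2, and the post hoc table."""

    effect: str
    F: float
    df1: float
    df2: float
    p: float
    p_uncorrected: float
    epsilon_gg: float
    mauchly_w: float | None
    sphericity_p: float | None
    sphericity_violated: bool
    partial_eta_squared: float
    posthoc: pd.DataFrame | None = None

    def df_string(self) -> str:
        """Reporting-style df, fractional when GG-corrected (e.g. '1.6, 40.5')."""
        if self.sphericity_violated:
            return f"{self.df1:.1f}, {self.df2:.1f}"
        return f"{self.df1:.0f}, {self.df2:.0f}"


def _as_grid(data) -> np.ndarray:
    y = np.asarray(data, dtype=float)
    if y.ndim < 2 or np.isnan(y).any():
        raise ValueError("need a complete subjects x levels grid (no missing cells)")
    if y.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    return y


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows spanning the complement of the constant."""
    q, _ = np.linalg.qr(np.column_stack([np.ones(k), np.eye(k)[:, : k - 1]]))
    return q[:, 1:].T


def _contrast_cov(y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """C S C' with S the sample covariance across subjects (rows of y)."""
    S = np.cov(y, rowvar=False, ddof=1)
    return C @ S @ C.T


def gg_epsilon(data: np.ndarray, C: np.ndarray | None = None) -> float:
    """Greenhouse-Geisser epsilon from the covariance of level differences.

    Clipped to [1/(k-1), 1]; a spherical covariance gives exactly 1 and a
    rank-1 covariance gives the lower bound.
    """
    y = _as_grid(data)
    k = y.shape[1]
    if k < 2:
        raise ValueError("need at least 2 levels")
    if k == 2:
        return 1.0
    C = _orthonormal_contrasts(k) if C is None else C
    E = _contrast_cov(y, C)
    d = E.shape[0]
    tr2 = np.trace(E) ** 2
    trsq = np.trace(E @ E)
    if trsq <= 0:
        if tr2 == 0:  # degenerate: no variance in any contrast
            return 1.0
        raise ValueError("degenerate contrast covariance")
    eps = tr2 / (d * trsq)
    return float(np.clip(eps, 1.0 / d, 1.0))


def mauchly_sphericity(data: np.ndarray, C: np.ndarray | None = None):
    """Mauchly's W and its chi-square p-value.

    Requires k >= 3 levels and more subjects than levels (otherwise the
    contrast covariance is singular).
    """
    y = _as_grid(data)
    n, k = y.shape[0], y.shape[1]
    if k < 3:
        raise ValueError("sphericity is trivial for k < 3")
    C = _orthonormal_contrasts(k) if C is None else C
    E = _contrast_cov(y, C)
    d = E.shape[0]
    det = np.linalg.det(E)
    tr = np.trace(E)
    if det <= 0 or tr <= 0:
        raise ValueError("singular contrast covariance; cannot test sphericity")
    W = det / (tr / d) ** d
    f = 1.0 - (2 * d * d + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f * np.log(W)
    df = d * (d + 1) // 2 - 1
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    return float(W), p


def bonferroni_posthoc(data: np.ndarray, level_names=None) -> pd.DataFrame:
    """All pairwise paired t-tests with Bonferroni-adjusted p-values."""
    y = _as_grid(data)
    k = y.shape[1]
    names = list(level_names) if level_names is not None else [str(i) for i in range(k)]
    pairs = list(combinations(range(k), 2))
    rows = []
    for i, j in pairs:
        diff = y[:, i] - y[:, j]
        if np.allclose(diff.std(ddof=1), 0):
            t, p = (0.0, 1.0) if np.allclose(diff.mean(), 0) else (np.inf, 0.0)
        else:
            t, p = sps.ttest_rel(y[:, i], y[:, j])
        p_adj = min(1.0, float(p) * len(pairs))
        rows.append({
            "A": names[i], "B": names[j],
            "mean_diff": float(diff.mean()),
            "t": float(t), "p_uncorrected": float(p),
            "p_bonferroni": p_adj, "significant": p_adj < ALPHA,
        })
    return pd.DataFrame(rows)


def _effect_result(effect, ss_eff, df1, ss_err, df2, level_data, C, n,
                   posthoc_data=None, level_names=None) -> AnovaResult:
    """Assemble one effect from its SS pair and the per-subject level data
    used for the sphericity diagnostics."""
    if ss_eff + ss_err <= 0:
        # constant data: no effect, no error
        F, p_unc, peta = 0.0, 1.0, 0.0
    elif ss_err == 0:
        F, p_unc, peta = np.inf, 0.0, 1.0
    else:
        F = (ss_eff / df1) / (ss_err / df2)
        p_unc = float(sps.f.sf(F, df1, df2))
        peta = ss_eff / (ss_eff + ss_err)

    d = C.shape[0] if C is not None else 1
    eps, W, sp = 1.0, None, None
    if d >= 2 and np.isfinite(F):
        try:
            eps = gg_epsilon(level_data, C)
            W, sp = mauchly_sphericity(level_data, C)
        except ValueError:
            pass
    violated = sp is not None and sp < ALPHA
    if violated:
        adj1, adj2 = eps * df1, eps * df2
        p = float(sps.f.sf(F, adj1, adj2)) if np.isfinite(F) else 0.0
        df1, df2 = adj1, adj2
    else:
        p = p_unc

    posthoc = None
    if p < ALPHA and posthoc_data is not None:
        posthoc = bonferroni_posthoc(posthoc_data, level_names)
    return AnovaResult(
        effect=effect, F=float(F), df1=float(df1), df2=float(df2), p=p,
        p_uncorrected=p_unc, epsilon_gg=float(eps), mauchly_w=W,
        sphericity_p=sp, sphericity_violated=violated,
        partial_eta_squared=float(peta), posthoc=posthoc,
    )


def rm_anova_oneway(data: np.ndarray, level_names=None) -> AnovaResult:
    """One-way repeated-measures ANOVA on a subjects x levels grid.

    GG correction is applied when Mauchly's p < 0.05; the Bonferroni post
    hoc runs only when the (possibly corrected) omnibus p < 0.05.
    """
    y = _as_grid(data)
    n, k = y.shape
    if k < 2:
        raise ValueError("need at least 2 levels")
    grand = y.mean()
    subj = y.mean(axis=1)
    cond = y.mean(axis=0)
    ss_total = float(((y - grand) ** 2).sum())
    ss_subj = float(k * ((subj - grand) ** 2).sum())
    ss_cond = float(n * ((cond - grand) ** 2).sum())
    ss_err = ss_total - ss_subj - ss_cond
    C = _orthonormal_contrasts(k) if k >= 3 else None
    return _effect_result(
        "condition", ss_cond, k - 1, max(ss_err, 0.0), (k - 1) * (n - 1),
        y, C, n, posthoc_data=y, level_names=level_names,
    )


def oneway_ss_decomposition(data: np.ndarray) -> dict:
    """The raw SS partition (for diagnostics and conservation checks)."""
    y = _as_grid(data)
    n, k = y.shape
    grand = y.mean()
    return {
        "ss_total": float(((y - grand) ** 2).sum()),
        "ss_subjects": float(k * ((y.mean(axis=1) - grand) ** 2).sum()),
        "ss_condition": float(n * ((y.mean(axis=0) - grand) ** 2).sum()),
        "ss_error": float(((y - y.mean(axis=1, keepdims=True)
                            - y.mean(axis=0) + grand) ** 2).sum()),
    }


def rm_anova_twoway(data: np.ndarray, a_names=None, b_names=None) -> dict:
    """Two-way fully-crossed within-subjects ANOVA on an (n, a, b) grid.

    Returns a dict with AnovaResult entries for the two main effects and
    the interaction, each tested against its own subject-by-factor error
    term and GG-corrected independently when its sphericity is violated.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 3:
        raise ValueError("need an (n_subjects, a_levels, b_levels) grid")
    if np.isnan(y).any():
        raise ValueError("missing cells are not supported")
    n, a, b = y.shape
    if n < 2 or a < 2 or b < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels per factor")

    g = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = float(n * b * ((m_a - g) ** 2).sum())
    ss_b = float(n * a * ((m_b - g) ** 2).sum())
    ss_ab = float(n * ((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2).sum())
    ss_as = float(b * ((m_sa - m_s[:, None] - m_a[None, :] + g) ** 2).sum())
    ss_bs = float(a * ((m_sb - m_s[:, None] - m_b[None, :] + g) ** 2).sum())
    ss_total = float(((y - g) ** 2).sum())
    ss_subj = float(a * b * ((m_s - g) ** 2).sum())
    ss_abs = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_as - ss_bs

    Ca = _orthonormal_contrasts(a) if a >= 3 else None
    Cb = _orthonormal_contrasts(b) if b >= 3 else None
    Cab = np.kron(
        _orthonormal_contrasts(a), _orthonormal_contrasts(b)
    )

    out = {
        "A": _effect_result("A", ss_a, a - 1, max(ss_as, 0.0), (a - 1) * (n - 1),
                            m_sa, Ca, n, posthoc_data=m_sa, level_names=a_names),
        "B": _effect_result("B", ss_b, b - 1, max(ss_bs, 0.0), (b - 1) * (n - 1),
                            m_sb, Cb, n, posthoc_data=m_sb, level_names=b_names),
        "AxB": _effect_result(
            "AxB", ss_ab, (a - 1) * (b - 1), max(ss_abs, 0.0),
            (a - 1) * (b - 1) * (n - 1),
            y.reshape(n, a * b), Cab, n,
        ),
    }
    return out


def anova_table(results) -> pd.DataFrame:
    """Flatten AnovaResult objects into a report table."""
    if isinstance(results, AnovaResult):
        results = [results]
    elif isinstance(results, dict):
        results = list(results.values())
    rows = []
    for r in results:
        rows.append({
            "effect": r.effect, "F": r.F, "df": r.df_string(), "p": r.p,
            "epsilon_GG": r.epsilon_gg, "sphericity_p": r.sphericity_p,
            "partial_eta_sq": r.partial_eta_squared,
        })
    return pd.DataFrame(rows)


def grid_from_long(df: pd.DataFrame, subject: str, factor: str, value: str):
    """Pivot a long-format table into the subjects x levels grid."""
    wide = df.pivot_table(index=subject, columns=factor, values=value)
    if wide.isna().any().any():
        raise ValueError("incomplete design: missing subject x level cells")
    return wide.to_numpy(), list(wide.columns)
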