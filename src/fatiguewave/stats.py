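"""Repeated-measures inference for within-subject session designs.

One- and two-way within-subject ANOVA from explicit sums of squares, with
the Greenhouse-Geisser sphericity correction applied unconditionally to
every effect (Mauchly's test is computed and reported as a diagnostic
only, never used as a gate), Fisher LSD post-hoc paired comparisons with
deliberately unadjusted p-values, and Pearson correlation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .errors import DegenerateInputError, SchemaError


@dataclass
class WithinSubjectTable:
    """A complete subject × condition matrix for a within-subject design.

    ``values`` has shape ``(n_subjects, k)`` for one factor or
    ``(n_subjects, a, b)`` for two fully crossed factors.  ``factors`` maps
    factor names to their ordered level labels.
    """

    values: np.ndarray
    factors: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (2, 3):
            raise SchemaError("values must be 2-D (one factor) or 3-D (two factors)")
        if np.any(~np.isfinite(self.values)):
            raise SchemaError("within-subject table must be complete (no NaN/inf)")
        if self.values.shape[0] < 2:
            raise SchemaError("need at least 2 subjects")
        if any(s < 2 for s in self.values.shape[1:]):
            raise SchemaError("each factor needs at least 2 levels")
        if not self.factors:
            names = ["factor1", "factor2"][: self.values.ndim - 1]
            self.factors = {
                nm: list(range(self.values.shape[i + 1]))
                for i, nm in enumerate(names)
            }

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        dv: str,
        within: str | Sequence[str],
        subject: str,
    ) -> "WithinSubjectTable":
        """Pivot a tidy long table into the subject × condition matrix.

        Raises :class:`SchemaError` if any subject × condition cell is
        missing or duplicated (the design must be fully crossed).
        """
        within = [within] if isinstance(within, str) else list(within)
        missing = [c for c in [dv, subject, *within] if c not in df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        pivot = df.pivot_table(
            index=subject, columns=within, values=dv, aggfunc="count",
            fill_value=0, observed=False,
        )
        if (pivot.values != 1).any():
            raise SchemaError("design is not fully crossed (missing/duplicate cells)")
        wide = df.pivot_table(index=subject, columns=within, values=dv,
                              observed=False)
        levels = (
            [list(wide.columns)]
            if len(within) == 1
            else [list(lv) for lv in wide.columns.levels]
        )
        values = wide.to_numpy()
        if len(within) == 2:
            values = values.reshape(values.shape[0], len(levels[0]), len(levels[1]))
        return cls(values=values, factors=dict(zip(within, levels)))


@dataclass
class MauchlyResult:
    """Mauchly's sphericity test: W statistic and chi-square approximation.

    ``W`` is NaN when the contrast covariance cannot be estimated
    nondegenerately (n − 1 < k − 1 or singular covariance).
    """

    W: float
    chi2: float
    df: int
    p: float


@dataclass
class RMANOVAResult:
    """One within-subject effect with its Greenhouse-Geisser correction."""

    effect: str
    F: float
    df_num: int
    df_den: int
    epsilon_gg: float
    df_num_corr: float
    df_den_corr: float
    p: float
    mauchly: MauchlyResult | None = None


def _as_matrix(table: "WithinSubjectTable | np.ndarray") -> np.ndarray:
    if isinstance(table, WithinSubjectTable):
        return table.values
    return np.asarray(table, dtype=float)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """Rows form an orthonormal basis of the subspace orthogonal to 1."""
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1.0)
        c[i] /= np.linalg.norm(c[i])
    return c


def _gg_epsilon(m: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from an orthonormal-contrast covariance."""
    d = m.shape[0]
    denom = d * float(np.sum(m * m))
    if denom <= 0.0:
        return 1.0
    eps = float(np.trace(m)) ** 2 / denom
    return min(1.0, max(1.0 / d, eps))


def mauchly(table: "WithinSubjectTable | np.ndarray") -> MauchlyResult:
    """Mauchly's test of sphericity on a one-factor subject × k matrix.

    Returns a diagnostic result with ``W = NaN`` when fewer subjects than
    contrast dimensions make the covariance estimate singular.
    """
    data = _as_matrix(table)
    n, k = data.shape
    df = k * (k - 1) // 2 - 1
    if k == 2:
        return MauchlyResult(W=1.0, chi2=0.0, df=df, p=1.0)
    c = _orthonormal_contrasts(k)
    s = np.cov(data, rowvar=False)
    m = c @ s @ c.T
    eigs = np.linalg.eigvalsh(m)
    if n - 1 < k - 1 or eigs.min() <= 1e-12 * max(eigs.max(), 1e-300):
        return MauchlyResult(W=math.nan, chi2=math.nan, df=df, p=math.nan)
    w = float(np.prod(eigs) / (eigs.mean() ** (k - 1)))
    # chi-square approximation with the second-order Box correction,
    # matching the SPSS / ezANOVA convention
    d = k - 1
    f_corr = 1.0 - (2.0 * d**2 + d + 2.0) / (6.0 * d * (n - 1))
    chi2 = -f_corr * (n - 1) * math.log(w)
    w2 = (
        (d + 2.0) * (d - 1.0) * (d - 2.0) * (2.0 * d**3 + 6.0 * d**2 + 3.0 * k + 2.0)
        / (288.0 * ((n - 1) * d * f_corr) ** 2)
    )
    p1 = float(sp_stats.chi2.sf(chi2, df))
    p2 = float(sp_stats.chi2.sf(chi2, df + 4))
    p = p1 + w2 * (p2 - p1)
    return MauchlyResult(W=w, chi2=chi2, df=df, p=p)


def _snap(ss: float, ss_total: float) -> float:
    """Zero out sums of squares that are pure floating-point residue."""
    return 0.0 if ss <= 1e-12 * max(ss_total, 1e-300) else ss


def _f_and_p(ss_eff: float, df1: int, ss_err: float, df2: int, eps: float):
    ms_eff = ss_eff / df1
    ms_err = ss_err / df2
    if ms_err == 0.0:
        if ms_eff == 0.0:
            return 0.0, 1.0
        return math.inf, 0.0  # infinite-F diagnostic: zero error mean-square
    f = ms_eff / ms_err
    p = float(sp_stats.f.sf(f, eps * df1, eps * df2))
    return f, p


def rm_anova_oneway(table: "WithinSubjectTable | np.ndarray",
                    effect: str = "condition") -> RMANOVAResult:
    """One-way within-subject ANOVA with unconditional GG correction.

    ``F = MS_condition / MS_(condition × subject)`` from the explicit
    decomposition ``SS_total = SS_subject + SS_condition + SS_error``.
    """
    data = _as_matrix(table)
    n, k = data.shape
    grand = data.mean()
    cond_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_cond = n * float(np.sum((cond_means - grand) ** 2))
    ss_subj = k * float(np.sum((subj_means - grand) ** 2))
    ss_total = float(np.sum((data - grand) ** 2))
    ss_err = max(ss_total - ss_cond - ss_subj, 0.0)
    ss_cond = _snap(ss_cond, ss_total)
    ss_err = _snap(ss_err, ss_total)
    df1, df2 = k - 1, (n - 1) * (k - 1)
    c = _orthonormal_contrasts(k)
    eps = _gg_epsilon(c @ np.cov(data, rowvar=False) @ c.T)
    f, p = _f_and_p(ss_cond, df1, ss_err, df2, eps)
    return RMANOVAResult(
        effect=effect, F=f, df_num=df1, df_den=df2, epsilon_gg=eps,
        df_num_corr=eps * df1, df_den_corr=eps * df2, p=p,
        mauchly=mauchly(data),
    )


def rm_anova_twoway(
    table: "WithinSubjectTable | np.ndarray",
    factor_names: tuple[str, str] = ("channel", "timepoint"),
) -> dict[str, RMANOVAResult]:
    """Two-way fully crossed within-subject ANOVA.

    Each effect (two main effects and the interaction) is tested against
    its own effect × subject error term and GG-corrected using the
    covariance of its orthonormal contrast scores.
    """
    data = _as_matrix(table)
    if data.ndim != 3:
        raise SchemaError("two-way ANOVA needs a (subjects, a, b) array")
    n, a, b = data.shape
    fa, fb = factor_names
    grand = data.mean()
    m_i = data.mean(axis=(1, 2))
    m_a = data.mean(axis=(0, 2))
    m_b = data.mean(axis=(0, 1))
    m_ia = data.mean(axis=2)
    m_ib = data.mean(axis=1)
    m_ab = data.mean(axis=0)

    ss_a = n * b * float(np.sum((m_a - grand) ** 2))
    ss_as = b * float(np.sum((m_ia - m_i[:, None] - m_a[None, :] + grand) ** 2))
    ss_b = n * a * float(np.sum((m_b - grand) ** 2))
    ss_bs = a * float(np.sum((m_ib - m_i[:, None] - m_b[None, :] + grand) ** 2))
    ss_ab = n * float(
        np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    )
    resid = (
        data
        - m_ia[:, :, None]
        - m_ib[:, None, :]
        - m_ab[None, :, :]
        + m_i[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_abs = float(np.sum(resid**2))

    ss_total = float(np.sum((data - grand) ** 2))
    ss_a, ss_as = _snap(ss_a, ss_total), _snap(ss_as, ss_total)
    ss_b, ss_bs = _snap(ss_b, ss_total), _snap(ss_bs, ss_total)
    ss_ab, ss_abs = _snap(ss_ab, ss_total), _snap(ss_abs, ss_total)

    ca = _orthonormal_contrasts(a)
    cb = _orthonormal_contrasts(b)
    flat = data.reshape(n, a * b)
    cov_flat = np.cov(flat, rowvar=False)

    def eff(name, ss_eff, df1, ss_err, contrasts, scores):
        m = contrasts @ np.cov(scores, rowvar=False) @ contrasts.T \
            if scores is not None else contrasts @ cov_flat @ contrasts.T
        eps = _gg_epsilon(m)
        df2 = df1 * (n - 1)
        f, p = _f_and_p(ss_eff, df1, ss_err, df2, eps)
        diag = mauchly(scores) if scores is not None and scores.shape[1] > 2 else None
        return RMANOVAResult(
            effect=name, F=f, df_num=df1, df_den=df2, epsilon_gg=eps,
            df_num_corr=eps * df1, df_den_corr=eps * df2, p=p, mauchly=diag,
        )

    results = {
        fa: eff(fa, ss_a, a - 1, ss_as, ca, m_ia),
        fb: eff(fb, ss_b, b - 1, ss_bs, cb, m_ib),
        f"{fa}*{fb}": eff(
            f"{fa}*{fb}", ss_ab, (a - 1) * (b - 1), ss_abs,
            np.kron(ca, cb), None,
        ),
    }
    return results


def lsd_posthoc(
    table: "WithinSubjectTable | np.ndarray", labels: Sequence | None = None
) -> pd.DataFrame:
    """Fisher LSD pairwise paired t-tests, p-values unadjusted by design.

    The unadjusted p-values follow the LSD convention; downstream reports
    flag this so the multiplicity is auditable.
    """
    data = _as_matrix(table)
    n, k = data.shape
    if labels is None:
        labels = (
            table.factors[next(iter(table.factors))]
            if isinstance(table, WithinSubjectTable)
            else list(range(k))
        )
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = data[:, i] - data[:, j]
        if np.all(diff == diff[0]):
            if diff[0] == 0.0:
                t, p = 0.0, 1.0
            else:
                t, p = math.inf * np.sign(diff[0]), 0.0
        else:
            t, p = sp_stats.ttest_rel(data[:, i], data[:, j])
        rows.append(
            {
                "level_a": labels[i],
                "level_b": labels[j],
                "mean_diff": float(diff.mean()),
                "t": float(t),
                "df": n - 1,
                "p_uncorrected": float(p),
            }
        )
    return pd.DataFrame(rows)


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with its t-distribution p-value."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise DegenerateInputError("constant input has no defined correlation")
    r, p = sp_stats.pearsonr(x, y)
    return float(r), float(p)
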