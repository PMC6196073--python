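"""Repeated-measures statistics for the opposition-movement design.

The experimental design is fully within-participant: every participant
performs all 12 tasks (4 target fingers x 3 target phalanges), 15 trials
each.  Trials are averaged within participant x task before inference, so
the participant is the experimental unit.  Three analyses are provided:

* a balanced two-way repeated-measures ANOVA (finger x phalanx) per measure,
  with Huynh-Feldt sphericity correction of the degrees of freedom;
* a one-way repeated-measures ANOVA per task with the two-level factor
  "moving effector" (thumb vs finger phalanx), equivalent to a paired t-test;
* post-hoc pairwise paired t-tests with Bonferroni (or Holm) correction.

Sums of squares are computed by direct partition of the balanced design,
which keeps every component (and their exact additivity) inspectable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import RESULT_KEY, ValidationError

__all__ = [
    "RmAnovaResult",
    "PairwiseResult",
    "participant_means",
    "huynh_feldt_epsilon",
    "greenhouse_geisser_epsilon",
    "rm_anova_1way",
    "rm_anova_2way",
    "rm_anova_effector",
    "posthoc_pairwise",
]


@dataclass
class RmAnovaResult:
    effect: str
    ss_effect: float
    ss_error: float
    df_effect: int
    df_error: int
    epsilon_hf: float
    f_value: float
    p_value: float  # epsilon-adjusted
    p_uncorrected: float
    adjusted_df: tuple[float, float]


@dataclass
class PairwiseResult:
    level_a: str
    level_b: str
    mean_diff: float  # mean(a) - mean(b)
    t_value: float
    p_raw: float
    p_adjusted: float
    method: str


# --------------------------------------------------------------------------
# Aggregation
# --------------------------------------------------------------------------

def participant_means(
    table: pd.DataFrame, measure: str | None = None
) -> pd.DataFrame:
    """Average the trial repetitions within participant x task x effector.

    Input is the long results table; output has one row per
    (participant, task, effector, measure) cell.  Every cell of the design
    must contain at least one trial.
    """
    df = table if measure is None else table[table["measure"] == measure]
    if df.empty:
        raise ValidationError(f"no rows for measure {measure!r}")
    cells = [c for c in RESULT_KEY if c != "trial"] + ["measure"]
    out = df.groupby(cells, as_index=False, observed=True)["value"].mean()
    expected = {
        c: df[c].unique() for c in ("participant", "task", "effector", "measure")
    }
    n_expected = int(np.prod([len(v) for v in expected.values()]))
    if len(out) != n_expected:
        raise ValidationError(
            f"incomplete design: {len(out)} filled cells, expected {n_expected}"
        )
    return out


# --------------------------------------------------------------------------
# Sphericity
# --------------------------------------------------------------------------

def _epsilon_gg_from_cov(S: np.ndarray, C: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the condition covariance ``S`` using
    orthonormal contrasts ``C`` ((k-1) x k or d x k for interactions)."""
    M = C @ S @ C.T
    d = M.shape[0]
    tr = np.trace(M)
    denom = d * np.trace(M @ M)
    if denom <= 0:
        return 1.0
    return float(tr**2 / denom)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal basis of the contrast space (Helmert, normalized)."""
    H = np.zeros((k - 1, k))
    for i in range(k - 1):
        H[i, : i + 1] = 1.0
        H[i, i + 1] = -(i + 1)
        H[i] /= np.linalg.norm(H[i])
    return H


def _epsilon_hf(eps_gg: float, n: int, d: int) -> float:
    """Huynh-Feldt epsilon from the Greenhouse-Geisser estimate; n subjects,
    d effect degrees of freedom.  Clipped to (0, 1]."""
    denom = d * (n - 1 - d * eps_gg)
    if denom <= 0:
        return 1.0
    eps = (n * d * eps_gg - 2.0) / denom
    return float(np.clip(eps, eps_gg, 1.0))


def greenhouse_geisser_epsilon(data: np.ndarray) -> float:
    """GG epsilon for an n x k matrix of within-subject condition scores."""
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if k < 2:
        raise ValueError("need at least two within-subject levels")
    if k == 2:
        return 1.0
    S = np.cov(data, rowvar=False)
    return _epsilon_gg_from_cov(S, _orthonormal_contrasts(k))


def huynh_feldt_epsilon(data: np.ndarray) -> float:
    """Huynh-Feldt epsilon for an n x k matrix of condition scores.

    Equals 1 exactly for two-level factors (a single difference score cannot
    violate sphericity).  With n <= k - 1 the condition covariance is
    singular and the estimate unreliable; a warning is emitted.
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if k == 2:
        return 1.0
    if n <= k - 1:
        warnings.warn(
            f"Huynh-Feldt epsilon unreliable: {n} subjects for {k} levels "
            "(singular condition covariance)",
            stacklevel=2,
        )
    return _epsilon_hf(greenhouse_geisser_epsilon(data), n, k - 1)


# --------------------------------------------------------------------------
# ANOVA
# --------------------------------------------------------------------------

def _adjusted_p(f: float, df1: int, df2: int, eps: float) -> tuple[float, tuple[float, float]]:
    adj = (eps * df1, eps * df2)
    if f <= 0:
        return 1.0, adj
    return float(sps.f.sf(f, *adj)), adj


def rm_anova_1way(data: np.ndarray, effect: str = "condition") -> RmAnovaResult:
    """One-way repeated-measures ANOVA on an n x k matrix (subjects x levels).

    F = MS_condition / MS_(condition x subject); with k = 2 this is exactly
    the squared paired t-statistic.
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if n < 2:
        raise ValidationError(f"need at least 2 participants, got {n}")
    if k < 2:
        raise ValidationError("need at least 2 within-subject levels")
    grand = data.mean()
    subj = data.mean(axis=1)
    cond = data.mean(axis=0)
    ss_cond = n * float(np.sum((cond - grand) ** 2))
    resid = data - subj[:, None] - cond[None, :] + grand
    ss_err = float(np.sum(resid**2))
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    f = ms_cond / ms_err if ms_err > 0 else 0.0
    eps = huynh_feldt_epsilon(data)
    p_unc = float(sps.f.sf(f, df1, df2)) if f > 0 else 1.0
    p_adj, adj_df = _adjusted_p(f, df1, df2, eps)
    return RmAnovaResult(effect, ss_cond, ss_err, df1, df2, eps, f, p_adj, p_unc, adj_df)


def _pivot_cells(
    cells: pd.DataFrame, value: str, index: str, columns: str | list[str]
) -> pd.DataFrame:
    wide = cells.pivot_table(index=index, columns=columns, values=value, observed=True)
    if wide.isna().any().any():
        raise ValidationError("incomplete design: empty participant x condition cell")
    return wide


def rm_anova_2way(
    cells: pd.DataFrame,
    value: str = "value",
    subject: str = "participant",
    factor_a: str = "finger",
    factor_b: str = "phalanx",
) -> dict[str, RmAnovaResult]:
    """Balanced two-way repeated-measures ANOVA (both factors within-subject).

    ``cells`` holds one row per subject x level_a x level_b.  Returns results
    for the two main effects and the interaction, each tested against its own
    interaction-with-subject error term, with per-effect Huynh-Feldt epsilon.
    """
    for col in (subject, factor_a, factor_b, value):
        if col not in cells.columns:
            raise ValidationError(f"missing column {col!r}")
    wide = _pivot_cells(cells, value, subject, [factor_a, factor_b])
    n = wide.shape[0]
    if n < 2:
        raise ValidationError(f"need at least 2 participants, got {n}")
    a_levels = wide.columns.get_level_values(0).unique()
    b_levels = wide.columns.get_level_values(1).unique()
    a, b = len(a_levels), len(b_levels)
    # cube: subjects x A x B
    Y = wide.to_numpy().reshape(n, a, b)

    grand = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_ab = Y.mean(axis=0)
    m_sa = Y.mean(axis=2)
    m_sb = Y.mean(axis=1)

    ss_a = n * b * float(np.sum((m_a - grand) ** 2))
    ss_b = n * a * float(np.sum((m_b - grand) ** 2))
    ss_ab = n * float(np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2))
    ss_s = a * b * float(np.sum((m_s - grand) ** 2))
    ss_as = b * float(
        np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    )
    ss_bs = a * float(
        np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    )
    resid = (
        Y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_abs = float(np.sum(resid**2))

    def _result(name: str, ss_eff: float, df_eff: int, ss_err: float, df_err: int,
                eps_data: np.ndarray) -> RmAnovaResult:
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        f = ms_eff / ms_err if ms_err > 0 else 0.0
        k_eff = eps_data.shape[1]
        if df_eff == 1 or k_eff == 2:
            eps = 1.0
        else:
            eps = _epsilon_hf(
                _epsilon_gg_from_cov(
                    np.cov(eps_data, rowvar=False), _contrasts_for(name, a, b)
                ),
                n,
                df_eff,
            )
        p_unc = float(sps.f.sf(f, df_eff, df_err)) if f > 0 else 1.0
        p_adj, adj_df = _adjusted_p(f, df_eff, df_err, eps)
        return RmAnovaResult(
            name, ss_eff, ss_err, df_eff, df_err, eps, f, p_adj, p_unc, adj_df
        )

    def _contrasts_for(name: str, a: int, b: int) -> np.ndarray:
        if name == factor_a:
            return _orthonormal_contrasts(a)
        if name == factor_b:
            return _orthonormal_contrasts(b)
        return np.kron(_orthonormal_contrasts(a), _orthonormal_contrasts(b))

    results = {
        factor_a: _result(factor_a, ss_a, a - 1, ss_as, (n - 1) * (a - 1), m_sa),
        factor_b: _result(factor_b, ss_b, b - 1, ss_bs, (n - 1) * (b - 1), m_sb),
        "interaction": _result(
            "interaction", ss_ab, (a - 1) * (b - 1), ss_abs, (n - 1) * (a - 1) * (b - 1),
            Y.reshape(n, a * b),
        ),
    }
    # exact partition check: total SS equals the sum of all components
    ss_total = float(np.sum((Y - grand) ** 2))
    parts = ss_a + ss_b + ss_ab + ss_s + ss_as + ss_bs + ss_abs
    if not np.isclose(ss_total, parts, rtol=1e-10, atol=1e-8):  # pragma: no cover
        raise AssertionError("sum-of-squares partition failed to add up")
    return results


def rm_anova_effector(
    cells: pd.DataFrame,
    value: str = "value",
    subject: str = "participant",
    factor: str = "effector",
) -> RmAnovaResult:
    """One-way RM ANOVA with the two-level moving-effector factor, for one
    task.  Equivalent to a paired t-test on thumb vs finger values."""
    wide = _pivot_cells(cells, value, subject, factor)
    if wide.shape[1] != 2:
        raise ValidationError(
            f"effector factor must have exactly 2 levels, got {list(wide.columns)}"
        )
    return rm_anova_1way(wide.to_numpy(), effect=factor)


# --------------------------------------------------------------------------
# Post-hoc comparisons
# --------------------------------------------------------------------------

def posthoc_pairwise(
    cells: pd.DataFrame,
    factor: str,
    value: str = "value",
    subject: str = "participant",
    method: str = "bonferroni",
) -> list[PairwiseResult]:
    """All-pairs paired t-tests between the levels of ``factor``.

    Values are averaged over any remaining design factors within subject
    before pairing.  ``method`` is ``"bonferroni"`` (default) or ``"holm"``.
    """
    if method not in ("bonferroni", "holm"):
        raise ValueError(f"unknown correction method {method!r}")
    wide = cells.pivot_table(
        index=subject, columns=factor, values=value, observed=True
    )
    if wide.isna().any().any():
        raise ValidationError("incomplete design for post-hoc comparisons")
    levels = list(wide.columns)
    pairs = list(itertools.combinations(levels, 2))
    raw = []
    for la, lb in pairs:
        diff = wide[la].to_numpy() - wide[lb].to_numpy()
        if np.allclose(diff, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(wide[la], wide[lb])
        raw.append((la, lb, float(np.mean(diff)), float(t), float(p)))

    m = len(raw)
    if method == "bonferroni":
        adjusted = [min(1.0, p * m) for *_, p in raw]
    else:  # holm step-down
        order = np.argsort([p for *_, p in raw])
        adjusted = [0.0] * m
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * raw[idx][4]))
            adjusted[idx] = running
    return [
        PairwiseResult(la, lb, d, t, p, p_adj, method)
        for (la, lb, d, t, p), p_adj in zip(raw, adjusted)
    ]
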