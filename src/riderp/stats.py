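"""Fully within-subjects repeated-measures ANOVA with Greenhouse-Geisser
correction, partial eta squared, simple main effects, and planned pairwise
comparisons.

The design is balanced and fully within: every subject contributes exactly
one value per cell of up to three crossed within factors.  Each effect is
tested against its own effect-by-subject interaction.  Sums of squares are
computed by the standard balanced-design partition (Moebius
inclusion-exclusion over marginal means).  For every effect with more than
one numerator degree of freedom the Greenhouse-Geisser epsilon is
estimated from the covariance of orthonormal contrast scores and both the
uncorrected and the corrected p value are reported.
"""
from __future__ import annotations

from itertools import chain, combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ParameterError, ValidationError

__all__ = [
    "rm_anova",
    "gg_epsilon",
    "partial_eta2",
    "planned_pairwise",
    "simple_effects",
]


def partial_eta2(ss_effect: float, ss_error: float) -> float:
    """Partial eta squared: SS_effect / (SS_effect + SS_error)."""
    if ss_effect < 0 or ss_error < 0:
        raise ParameterError("sums of squares must be non-negative")
    if ss_effect == 0 and ss_error == 0:
        raise ParameterError("ss_effect and ss_error cannot both be zero")
    return ss_effect / (ss_effect + ss_error)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) matrix of orthonormal contrasts (columns sum to 0)."""
    q, _ = np.linalg.qr(np.eye(k) - 1.0 / k)
    return q[:, : k - 1]


def gg_epsilon(cell_matrix: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a subject x level matrix.

    epsilon-hat = (sum lambda)^2 / ((k-1) * sum lambda^2) over the
    eigenvalues of the covariance of the orthonormal-contrast scores,
    clipped to [1/(k-1), 1].
    """
    Y = np.asarray(cell_matrix, dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 2:
        raise ParameterError("need a subject x level matrix with >= 2 levels")
    K = _orthonormal_contrasts(Y.shape[1])
    return _gg_from_scores(Y @ K)


def _gg_from_scores(Z: np.ndarray) -> float:
    q = Z.shape[1]
    if q == 1:
        return 1.0
    S = np.cov(Z, rowvar=False)
    lam = np.clip(np.linalg.eigvalsh(S), 0.0, None)
    denom = q * float((lam**2).sum())
    if denom == 0:
        return 1.0
    eps = float(lam.sum()) ** 2 / denom
    return float(np.clip(eps, 1.0 / q, 1.0))


def _effect_ss(Y: np.ndarray, effect_axes: tuple[int, ...]) -> float:
    """SS of one effect in a complete balanced tensor, via inclusion-exclusion."""
    all_axes = tuple(range(Y.ndim))
    est = np.zeros_like(Y, shape=tuple(
        Y.shape[a] if a in effect_axes else 1 for a in all_axes
    ))
    for r in range(len(effect_axes) + 1):
        for sub in combinations(effect_axes, r):
            sign = (-1) ** (len(effect_axes) - len(sub))
            m = Y.mean(axis=tuple(a for a in all_axes if a not in sub), keepdims=True)
            est = est + sign * m
    scale = np.prod([Y.shape[a] for a in all_axes if a not in effect_axes])
    return float((est**2).sum() * scale)


def _tensor_from_table(t: pd.DataFrame, factors, dv, subject):
    missing = [c for c in [subject, dv, *factors] if c not in t.columns]
    if missing:
        raise ValidationError(f"table is missing column(s): {missing}")
    t = t.copy()
    for c in [subject, *factors]:
        t[c] = t[c].astype(str)
    levels = {f: sorted(t[f].unique()) for f in factors}
    subjects = sorted(t[subject].unique())
    counts = t.groupby([subject, *factors], observed=True).size()
    expected = len(subjects) * int(np.prod([len(v) for v in levels.values()]))
    if len(counts) != expected or (counts != 1).any():
        full = pd.MultiIndex.from_product(
            [subjects, *levels.values()], names=[subject, *factors]
        )
        got = pd.MultiIndex.from_frame(
            t[[subject, *factors]].astype(str)
        )
        absent = [tuple(ix) for ix in full if tuple(ix) not in set(map(tuple, got))]
        raise ValidationError(
            f"unbalanced table: each subject x cell must appear exactly once; "
            f"missing cells: {absent[:10]}{'...' if len(absent) > 10 else ''}"
        )
    piv = t.pivot_table(index=subject, columns=list(factors), values=dv, sort=True)
    Y = piv.to_numpy().reshape([len(subjects)] + [len(levels[f]) for f in factors])
    return Y, levels, subjects


def _anova_from_tensor(Y: np.ndarray, factor_names: list[str]) -> pd.DataFrame:
    """Within-subjects ANOVA from a (subject, f1, ..., fk) cell-mean tensor."""
    n = Y.shape[0]
    if n < 2:
        raise ParameterError("need at least 2 subjects")
    k = len(factor_names)
    rows = []
    factor_axes = {factor_names[i]: i + 1 for i in range(k)}
    effects = [
        eff for eff in chain.from_iterable(
            combinations(factor_names, r) for r in range(1, k + 1)
        )
    ]
    contrasts = {f: _orthonormal_contrasts(Y.shape[factor_axes[f]]) for f in factor_names}
    # sums of squares below the cancellation noise of the total SS are zero
    ss_floor = 1e-12 * float(((Y - Y.mean()) ** 2).sum())
    for eff in effects:
        axes = tuple(factor_axes[f] for f in eff)
        ss_eff = _effect_ss(Y, axes)
        ss_err = _effect_ss(Y, (0,) + axes)
        ss_eff = 0.0 if ss_eff < ss_floor else ss_eff
        ss_err = 0.0 if ss_err < ss_floor else ss_err
        df_num = int(np.prod([Y.shape[a] - 1 for a in axes]))
        df_den = df_num * (n - 1)
        ms_eff = ss_eff / df_num
        ms_err = ss_err / df_den
        F = ms_eff / ms_err if ms_err > 0 else (0.0 if ms_eff == 0 else np.inf)
        # contrast scores for GG: average out the non-effect factors
        other = [a for a in range(1, k + 1) if a not in axes]
        M = Y.mean(axis=tuple(other)) if other else Y
        M = np.moveaxis(M, 0, 0).reshape(n, -1)
        K = contrasts[eff[0]]
        for f in eff[1:]:
            K = np.kron(K, contrasts[f])
        eps = _gg_from_scores(M @ K)
        p_unc = float(sps.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0
        p_gg = (
            float(sps.f.sf(F, df_num * eps, df_den * eps)) if np.isfinite(F) else 0.0
        )
        rows.append(
            dict(
                effect=" x ".join(eff),
                df_num=df_num,
                df_den=df_den,
                F=float(F),
                p_uncorrected=p_unc,
                gg_epsilon=eps,
                p_gg=p_gg,
                partial_eta2=partial_eta2(ss_eff, ss_err)
                if (ss_eff > 0 or ss_err > 0)
                else 0.0,
                ss_effect=ss_eff,
                ss_error=ss_err,
            )
        )
    return pd.DataFrame(rows)


def rm_anova(
    t: pd.DataFrame,
    factors: list[str],
    dv: str = "amplitude",
    subject: str = "subject",
) -> pd.DataFrame:
    """Repeated-measures ANOVA on a balanced long table.

    ``t`` has one row per subject x cell with columns ``subject``, one per
    within factor, and the dependent variable.  Returns a table with one
    row per effect: df, F, uncorrected p, Greenhouse-Geisser epsilon,
    corrected p, and partial eta squared.
    """
    if not 1 <= len(factors) <= 3:
        raise ParameterError("1-3 within factors supported")
    Y, _, _ = _tensor_from_table(t, factors, dv, subject)
    return _anova_from_tensor(Y, list(factors))


def planned_pairwise(
    t: pd.DataFrame,
    within: str = "condition",
    at: str | None = None,
    unit_col: str = "unit",
    dv: str = "amplitude",
    subject: str = "subject",
    adjust: str | None = None,
) -> pd.DataFrame:
    """Paired two-sided t-tests between condition pairs, per unit.

    ``at`` restricts to one electrode/ROI (otherwise every unit present is
    tested).  P values are uncorrected by default; ``adjust='holm'``
    applies the Holm step-down adjustment across all reported pairs.
    A pair whose within-subject differences have zero variance is flagged
    in the ``degenerate`` column (t undefined unless the mean is also 0).
    """
    units = [at] if at is not None else (
        sorted(t[unit_col].astype(str).unique()) if unit_col in t.columns else [None]
    )
    rows = []
    for unit in units:
        sub = t if unit is None else t[t[unit_col].astype(str) == unit]
        piv = sub.pivot_table(index=subject, columns=within, values=dv)
        conds = list(piv.columns)
        for i in range(len(conds)):
            for j in range(i + 1, len(conds)):
                a, b = piv[conds[i]], piv[conds[j]]
                paired = pd.concat([a, b], axis=1).dropna()
                if len(paired) < 2:
                    warnings_row = dict(
                        unit=unit, a=conds[i], b=conds[j], n=len(paired),
                        t=np.nan, df=np.nan, p=np.nan, degenerate=True,
                    )
                    rows.append(warnings_row)
                    continue
                diff = paired.iloc[:, 0] - paired.iloc[:, 1]
                degenerate = bool(np.isclose(diff.std(ddof=1), 0.0))
                if degenerate:
                    tval, p = (0.0, 1.0) if np.isclose(diff.mean(), 0) else (np.inf, 0.0)
                else:
                    tval, p = sps.ttest_rel(paired.iloc[:, 0], paired.iloc[:, 1])
                rows.append(
                    dict(
                        unit=unit, a=conds[i], b=conds[j], n=len(paired),
                        t=float(tval), df=len(paired) - 1, p=float(p),
                        degenerate=degenerate,
                    )
                )
    out = pd.DataFrame(rows)
    if adjust == "holm" and len(out):
        from statsmodels.stats.multitest import multipletests

        ok = out["p"].notna()
        adj = np.full(len(out), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(out.loc[ok, "p"], method="holm")[1]
        out["p_holm"] = adj
    return out


def simple_effects(
    t: pd.DataFrame,
    of: str = "condition",
    within_levels_of: str = "unit",
    dv: str = "amplitude",
    subject: str = "subject",
) -> dict[str, pd.DataFrame]:
    """One-way rm-ANOVA of ``of`` inside each level of ``within_levels_of``.

    Returns level -> ANOVA table (GG-corrected), e.g. the condition effect
    tested separately in every ROI.
    """
    out = {}
    for level in sorted(t[within_levels_of].astype(str).unique()):
        sub = t[t[within_levels_of].astype(str) == level]
        out[level] = rm_anova(sub, [of], dv=dv, subject=subject)
    return out
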