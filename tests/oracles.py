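"""Independent brute-force oracles for the within-subjects ANOVA.

Deliberately written along a different route than the package: sums of
squares come from the classical scaled-marginal-mean identity

    R(T) = (N / #cells(T)) * sum over cells of T of mean(cell)^2
    SS(E) = sum over subsets T of E of (-1)^{|E|-|T|} R(T)

computed with pandas groupby and explicit subset loops, and the
Greenhouse-Geisser epsilon for main effects comes from Box's
double-centering formula on the raw level covariance (no contrast
matrices, no eigenvalues).
"""
from itertools import chain, combinations

import numpy as np
from scipy import stats as sps


def _subsets(names):
    return chain.from_iterable(combinations(names, r) for r in range(len(names) + 1))


def _scaled_marginal_ss(df, by, dv):
    n_total = len(df)
    if not by:
        return n_total * df[dv].mean() ** 2
    means = df.groupby(list(by), observed=True)[dv].mean()
    return n_total / len(means) * float((means**2).sum())


def brute_force_rm_anova(df, factors, dv="amplitude", subject="subject"):
    """Effect -> dict(ss, df, ss_err, df_err, F, partial_eta2)."""
    df = df.copy()
    for c in [subject, *factors]:
        df[c] = df[c].astype(str)
    n_subj = df[subject].nunique()
    levels = {f: df[f].nunique() for f in factors}
    out = {}
    for eff in _subsets(factors):
        if not eff:
            continue
        ss = sum(
            (-1) ** (len(eff) - len(t)) * _scaled_marginal_ss(df, t, dv)
            for t in _subsets(eff)
        )
        err_set = (subject,) + eff
        ss_err = sum(
            (-1) ** (len(err_set) - len(t)) * _scaled_marginal_ss(df, t, dv)
            for t in _subsets(err_set)
        )
        df_num = int(np.prod([levels[f] - 1 for f in eff]))
        df_den = df_num * (n_subj - 1)
        F = (ss / df_num) / (ss_err / df_den)
        out[" x ".join(eff)] = dict(
            ss=ss, df_num=df_num, ss_err=ss_err, df_den=df_den, F=F,
            partial_eta2=ss / (ss + ss_err),
        )
    return out


def box_epsilon(Y):
    """GG epsilon by Box's double-centering formula (subject x level matrix)."""
    Y = np.asarray(Y, dtype=float)
    k = Y.shape[1]
    S = np.cov(Y, rowvar=False)
    row = S.mean(axis=0)
    centred = S - row[None, :] - row[:, None] + S.mean()
    num = np.trace(centred) ** 2
    den = (k - 1) * float((centred**2).sum())
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def paired_t_f(Y2):
    """Squared paired-t for a subject x 2 matrix (2-level one-way oracle)."""
    t = sps.ttest_rel(Y2[:, 0], Y2[:, 1]).statistic
    return float(t**2)
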