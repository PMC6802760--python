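"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's own code paths (and the library calls
behind them) so that agreement is evidence of correctness, not tautology.
"""

import numpy as np
from scipy import stats as sps


def mixed_anova_oracle(table, dv="span"):
    """Classical sums-of-squares mixed ANOVA for a balanced 2 x k design.

    Returns (effects dict, ss partition residual). Effects are keyed
    'between'/'within'/'interaction' with (F, df1, df2, p).
    """
    piv = table.pivot(index="participant_id", columns="complexity", values=dv)
    groups = (table.groupby("participant_id")["age_group"].first()
              .reindex(piv.index).to_numpy())
    y = piv.to_numpy(float)
    n_subj, k = y.shape
    labels = np.unique(groups)
    grand = y.mean()
    subj_means = y.mean(axis=1)
    col_means = y.mean(axis=0)

    ss_total = ((y - grand) ** 2).sum()
    ss_between_subj = k * ((subj_means - grand) ** 2).sum()
    ss_age = sum((groups == g).sum() * k
                 * (subj_means[groups == g].mean() - grand) ** 2
                 for g in labels)
    ss_subj_err = ss_between_subj - ss_age
    ss_within = ss_total - ss_between_subj
    ss_comp = n_subj * ((col_means - grand) ** 2).sum()
    ss_inter = sum(
        (groups == g).sum()
        * ((y[groups == g].mean(axis=0) - col_means
            - y[groups == g].mean() + grand) ** 2).sum()
        for g in labels)
    ss_werr = ss_within - ss_comp - ss_inter

    df_age, df_serr = len(labels) - 1, n_subj - len(labels)
    df_comp = k - 1
    df_inter = (len(labels) - 1) * (k - 1)
    df_werr = (k - 1) * (n_subj - len(labels))

    def eff(ss, df1, ss_err, df2):
        f = (ss / df1) / (ss_err / df2)
        return {"F": f, "df1": df1, "df2": df2,
                "p": float(sps.f.sf(f, df1, df2))}

    effects = {
        "between": eff(ss_age, df_age, ss_subj_err, df_serr),
        "within": eff(ss_comp, df_comp, ss_werr, df_werr),
        "interaction": eff(ss_inter, df_inter, ss_werr, df_werr),
    }
    partition_residual = abs(
        ss_total - (ss_age + ss_subj_err + ss_comp + ss_inter + ss_werr))
    return effects, partition_residual


def span_by_grid_scan(fit_fn, criterion, lo=-9.0, hi=9.0, step=1e-3):
    """Outermost criterion crossings by linear interpolation on a dense grid."""
    x = np.arange(lo, hi + step / 2, step)
    y = np.asarray(fit_fn(x), float) - criterion
    if y.max() < 0:
        return 0.0
    above = np.flatnonzero(y >= 0)
    i0, i1 = above[0], above[-1]
    if i0 == 0:
        x_l = x[0]
    else:
        x_l = x[i0 - 1] + step * (-y[i0 - 1]) / (y[i0] - y[i0 - 1])
    if i1 == len(x) - 1:
        x_r = x[-1]
    else:
        x_r = x[i1] + step * y[i1] / (y[i1] - y[i1 + 1])
    return x_r - x_l


def info_bits_oracle(p, n):
    """Mutual information of the uniform-confusion channel, direct evaluation."""
    p = min(max(p, 1.0 / n), 1.0)
    total = np.log2(n) + p * np.log2(p)
    if p < 1.0:
        total += (1 - p) * np.log2((1 - p) / (n - 1))
    return float(total)


def gaussian_grid_fit_r2(x, y, amps, mus, sigmas):
    """Best r^2 of a single Gaussian over a brute-force parameter grid."""
    x = np.asarray(x, float)[None, :]
    best_ss = np.inf
    mu_g, sg_g = np.meshgrid(mus, sigmas, indexing="ij")
    shapes = np.exp(-((x - mu_g.ravel()[:, None]) ** 2)
                    / (2 * sg_g.ravel()[:, None] ** 2))
    for a in amps:
        ss = ((a * shapes - y[None, :]) ** 2).sum(axis=1)
        best_ss = min(best_ss, float(ss.min()))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - best_ss / ss_tot
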