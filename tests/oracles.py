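"""Independent brute-force oracles used by the tests.

Each of these recomputes a quantity by direct enumeration or a textbook
formula, deliberately sharing no code with the package implementation.
"""

import numpy as np


def glcm_brute(levels, mask, directions, offsets, ng, symmetric=True):
    """Co-occurrence counts by looping over every voxel and displacement."""
    counts = np.zeros((ng, ng), dtype=np.int64)
    shape = levels.shape
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                for d in directions:
                    for o in offsets:
                        zz, yy, xx = z + d[0] * o, y + d[1] * o, x + d[2] * o
                        if not (0 <= zz < shape[0] and 0 <= yy < shape[1]
                                and 0 <= xx < shape[2]):
                            continue
                        if not mask[zz, yy, xx]:
                            continue
                        i, j = levels[z, y, x] - 1, levels[zz, yy, xx] - 1
                        counts[i, j] += 1
                        if symmetric:
                            counts[j, i] += 1
    return counts


def ngtdm_brute(levels, mask, d, ng):
    """Per-level n_i and s_i by explicit neighbourhood loops."""
    shape = levels.shape
    n = np.zeros(ng, dtype=np.int64)
    s = np.zeros(ng, dtype=float)
    n_valid = 0
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                neigh = []
                for dz in range(-d, d + 1):
                    for dy in range(-d, d + 1):
                        for dx in range(-d, d + 1):
                            if dz == dy == dx == 0:
                                continue
                            zz, yy, xx = z + dz, y + dy, x + dx
                            if (0 <= zz < shape[0] and 0 <= yy < shape[1]
                                    and 0 <= xx < shape[2] and mask[zz, yy, xx]):
                                neigh.append(levels[zz, yy, xx])
                if not neigh:
                    continue
                n_valid += 1
                g = levels[z, y, x]
                n[g - 1] += 1
                s[g - 1] += abs(g - float(np.mean(neigh)))
    return n, s, n_valid


def anova_mean_squares_long(values):
    """Two-way ANOVA mean squares via statsmodels OLS on long-format data."""
    import pandas as pd
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    n, k = values.shape
    long = pd.DataFrame({
        "y": values.ravel(),
        "subject": np.repeat(np.arange(n), k),
        "rater": np.tile(np.arange(k), n),
    })
    model = ols("y ~ C(subject) + C(rater)", data=long).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    msr = tab.loc["C(subject)", "sum_sq"] / tab.loc["C(subject)", "df"]
    msc = tab.loc["C(rater)", "sum_sq"] / tab.loc["C(rater)", "df"]
    mse = tab.loc["Residual", "sum_sq"] / tab.loc["Residual", "df"]
    return float(msr), float(msc), float(mse)


def efron_log_partial_likelihood(beta, time, event, z):
    """Efron-tie-corrected Cox log partial likelihood for one covariate."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    z = np.asarray(z, float)
    theta = np.exp(beta * z)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        dead = (time == t) & (event == 1)
        at_risk = time >= t
        m = int(dead.sum())
        sum_dead_z = z[dead].sum()
        risk_sum = theta[at_risk].sum()
        tie_sum = theta[dead].sum()
        ll += beta * sum_dead_z
        for ell in range(m):
            ll -= np.log(risk_sum - (ell / m) * tie_sum)
    return ll


def efron_beta_grid(time, event, z, lo=-5.0, hi=5.0, tol=1e-6):
    """Maximise the Efron partial likelihood by golden-section search."""
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda b: -efron_log_partial_likelihood(b, time, event, z),
        bounds=(lo, hi), method="bounded",
        options={"xatol": tol},
    )
    return float(res.x)
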