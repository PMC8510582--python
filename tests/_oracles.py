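"""Independent numerical oracles used by the tests.

These deliberately avoid the code paths they check: the inverse normal
CDF is computed by bisection on ``scipy``'s CDF rather than ``ppf``, and
Monte-Carlo oracles are written inline with plain numpy.
"""

import numpy as np
from scipy.stats import norm


def bisect_norm_ppf(p: float, lo: float = -12.0, hi: float = 12.0, tol: float = 1e-12) -> float:
    """Quantile of the standard normal by bisection on the CDF."""
    assert 0.0 < p < 1.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if norm.cdf(mid) < p:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def mc_risk_lrp_given_c(K, r2, n, c, n_draws, seed):
    """Monte-Carlo risk of the minimum-score embryo at fixed c."""
    rng = np.random.default_rng(seed)
    z_K = bisect_norm_ppf(1.0 - K)
    x = rng.normal(0.0, np.sqrt(r2 / 2.0), (n_draws, n))
    s_min = c + x.min(axis=1)
    y = s_min + rng.normal(0.0, np.sqrt(1.0 - r2), n_draws)
    p = float(np.mean(y > z_K))
    se = np.sqrt(p * (1.0 - p) / n_draws)
    return p, se


def mc_risk_random_given_c(K, r2, c, n_draws, seed):
    """Monte-Carlo risk of a single random embryo at fixed c."""
    rng = np.random.default_rng(seed)
    z_K = bisect_norm_ppf(1.0 - K)
    s = c + rng.normal(0.0, np.sqrt(r2 / 2.0), n_draws)
    y = s + rng.normal(0.0, np.sqrt(1.0 - r2), n_draws)
    p = float(np.mean(y > z_K))
    se = np.sqrt(p * (1.0 - p) / n_draws)
    return p, se


def mc_offspring_risk_given_status(K, h2, r2, n, affected1, affected2, n_couples, seed):
    """Rejection-sampling oracle for parental-status conditioning.

    Simulates parental (score, non-score genetic, environment) triples,
    keeps couples matching the statuses, and simulates n embryos with
    mid-parental transmission; returns (risk of random embryo, risk of
    the minimum-PRS embryo, binomial SE scale).
    """
    rng = np.random.default_rng(seed)
    z_K = bisect_norm_ppf(1.0 - K)
    want = np.array([affected1, affected2])
    kept_c, kept_d = [], []
    total = 0
    while total < n_couples:
        m = 200_000
        s = rng.normal(0.0, np.sqrt(r2), (m, 2))
        g = rng.normal(0.0, np.sqrt(h2 - r2), (m, 2)) if h2 > r2 else np.zeros((m, 2))
        env = rng.normal(0.0, np.sqrt(1.0 - h2), (m, 2))
        ok = (((s + g + env) > z_K) == want).all(axis=1)
        kept_c.append(s[ok].mean(axis=1))
        kept_d.append(g[ok].mean(axis=1))
        total += int(ok.sum())
    c = np.concatenate(kept_c)[:n_couples]
    d = np.concatenate(kept_d)[:n_couples]
    x = rng.normal(0.0, np.sqrt(r2 / 2.0), (n_couples, n))
    g_seg = rng.normal(0.0, np.sqrt((h2 - r2) / 2.0), (n_couples, 2))
    e = rng.normal(0.0, np.sqrt(1.0 - h2), (n_couples, 2))
    # arm 0: first embryo (random); arm 1: minimum-PRS embryo
    y_rand = c + x[:, 0] + d + g_seg[:, 0] + e[:, 0]
    y_sel = c + x.min(axis=1) + d + g_seg[:, 1] + e[:, 1]
    p_rand = float(np.mean(y_rand > z_K))
    p_sel = float(np.mean(y_sel > z_K))
    se = np.sqrt(max(p_rand, p_sel) / n_couples)
    return p_rand, p_sel, se
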