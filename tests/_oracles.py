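"""Independent oracles used only by the tests.

These deliberately avoid the package's own fitting/test code paths:
the decay-fit oracle is a staged dense grid search over (s0, T) SSE,
and the trend-test oracle is a label-permutation Monte Carlo.
"""

from __future__ import annotations

import numpy as np


def grid_search_decay(
    signals: np.ndarray,
    tsl_ms: np.ndarray,
    s0_range: tuple[float, float] = (80.0, 120.0),
    t_range: tuple[float, float] = (40.0, 120.0),
    final_step: float = 0.01,
) -> tuple[float, float]:
    """Brute-force SSE minimiser for S0*exp(-TSL/T) on a dense grid.

    The S0 dimension is profiled in closed form (the model is linear in
    S0, so the optimal S0 on the grid's s0-axis limit is the exact
    least-squares amplitude, clipped to the search box), which makes the
    search over T global: the SSE valley runs diagonally in (S0, T) and
    a naive coarse-to-fine box refinement can lose it.
    """
    signals = np.asarray(signals, dtype=float)
    tsl = np.asarray(tsl_ms, dtype=float)
    ts = np.arange(t_range[0], t_range[1] + final_step / 2, final_step)
    basis = np.exp(-tsl[None, :] / ts[:, None])  # (n_t, n_tsl)
    s0_opt = (basis @ signals) / (basis * basis).sum(axis=1)
    s0_opt = np.clip(s0_opt, *s0_range)
    sse = ((s0_opt[:, None] * basis - signals[None, :]) ** 2).sum(axis=1)
    j = int(np.argmin(sse))
    return float(s0_opt[j]), float(ts[j])


def permutation_trend_p(
    counts: np.ndarray, n_perm: int = 20000, seed: int = 0
) -> float:
    """Two-sided permutation p-value for the 2xK ordered-table trend.

    The test statistic is the score sum of row 1 (equivalent to the
    standardised trend statistic under fixed margins); group labels are
    permuted over the pooled individual-level data.
    """
    counts = np.asarray(counts, dtype=int)
    K = counts.shape[1]
    scores = np.arange(1, K + 1, dtype=float)
    values = np.repeat(scores, counts.sum(axis=0))
    n1 = int(counts[0].sum())
    obs = float(scores @ counts[0])
    rng = np.random.default_rng(seed)
    stat = np.empty(n_perm)
    for b in range(n_perm):
        stat[b] = rng.permutation(values)[:n1].sum()
    # two-sided mid-p: distance from the permutation mean, with ties
    # counted half so the discrete distribution is comparable with a
    # continuous (normal) approximation
    dev = np.abs(stat - stat.mean())
    obs_dev = abs(obs - stat.mean())
    greater = (dev > obs_dev + 1e-9).mean()
    ties = (np.abs(dev - obs_dev) <= 1e-9).mean()
    return float(greater + 0.5 * ties)
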