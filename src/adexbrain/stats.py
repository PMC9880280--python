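"""Rank-based statistics helpers.

Currently the Conover-Iman post-hoc test for pairwise multiple comparisons
following a Kruskal-Wallis omnibus test, implemented from the standard
rank-statistic formulation.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def conover_posthoc(groups: Sequence[np.ndarray],
                    labels: Optional[Sequence[str]] = None,
                    p_adjust: str = "holm") -> pd.DataFrame:
    """Pairwise Conover-Iman test after Kruskal-Wallis.

    For groups of sizes n_i with pooled rank means R_i, the statistic for the
    pair (i, j) is

        t_ij = (R_i - R_j) / sqrt(S^2 (N - 1 - H)/(N - k) (1/n_i + 1/n_j)),

    referred to a t distribution with N - k degrees of freedom; S^2 is the
    variance of the (tie-corrected) pooled ranks and H the Kruskal-Wallis
    statistic.  Returns a symmetric DataFrame of (optionally Holm-adjusted)
    two-sided p-values with unit diagonal.
    """
    groups = [np.asarray(g, float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    ns = np.array([g.size for g in groups])
    if np.any(ns < 2):
        raise ValueError("each group needs at least two observations")
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    bounds = np.cumsum(ns)[:-1]
    rank_groups = np.split(ranks, bounds)
    Rbar = np.array([r.mean() for r in rank_groups])

    H = stats.kruskal(*groups).statistic
    S2 = ranks.var(ddof=1)
    dof = N - k
    denom_scale = S2 * (N - 1 - H) / dof
    if denom_scale <= 0:
        denom_scale = np.finfo(float).tiny

    pvals = np.ones((k, k))
    tstats = np.zeros((k, k))
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    raw = []
    for i, j in pairs:
        se = np.sqrt(denom_scale * (1.0 / ns[i] + 1.0 / ns[j]))
        t = (Rbar[i] - Rbar[j]) / se
        tstats[i, j] = tstats[j, i] = t
        raw.append(2.0 * stats.t.sf(abs(t), dof))
    raw = np.array(raw)
    if p_adjust == "holm":
        m = len(raw)
        adj = raw.copy()
        # Holm step-down: adjust in increasing p order, enforce monotonicity
        srt = np.argsort(raw)
        running = 0.0
        for rank_pos, idx in enumerate(srt):
            val = min(1.0, (m - rank_pos) * raw[idx])
            running = max(running, val)
            adj[idx] = running
        raw = adj
    elif p_adjust not in (None, "none"):
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    for (i, j), p in zip(pairs, raw):
        pvals[i, j] = pvals[j, i] = p

    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    return pd.DataFrame(pvals, index=labels, columns=labels)
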