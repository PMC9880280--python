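"""Spectral, correlation, phase and distance-profile analyses of regional activity.

All functions accept either a :class:`~adexbrain.brain_network.RegionalTimeSeries`
or a plain (n_regions, n_samples) array plus sampling rate.  Constant-rate
regions (zero variance) yield NaN entries that are flagged and excluded from
summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

__all__ = ["FCMatrix", "power_spectrum", "fc_pearson", "pli",
           "distance_profile", "compare_populations"]


@dataclass
class FCMatrix:
    """Functional-connectivity matrix with its metric and population tags.

    Pearson matrices are symmetric with unit diagonal in [-1, 1]; PLI
    matrices are symmetric with zero diagonal in [0, 1].
    """

    values: np.ndarray
    metric: str                  # "pearson" | "pli"
    population: str = "e"

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def offdiag(self) -> np.ndarray:
        """Upper-triangle off-diagonal entries (finite only)."""
        iu = np.triu_indices(self.n_regions, 1)
        vals = self.values[iu]
        return vals[np.isfinite(vals)]

    def mean_offdiag(self) -> float:
        return float(self.offdiag().mean())

    def to_csv(self, path) -> None:
        np.savetxt(path, self.values, delimiter=",")


def _as_array(series):
    """Accept RegionalTimeSeries or array; return (array, fs_hz)."""
    if hasattr(series, "nu_e"):
        return np.asarray(series.nu_e, float), series.fs
    return np.asarray(series, float), None


def power_spectrum(series, fs: float = None, population: str = "e",
                   window_s: float = 4.0, f_range=(0.1, 100.0)):
    """Welch power spectrum of the region-averaged rate.

    Hann windows of ``window_s`` seconds with 50% overlap.  Returns
    (frequencies Hz, power, peak_frequency) with the peak searched inside
    ``f_range``.  The series must cover at least one window.
    """
    if hasattr(series, "nu_e"):
        x = series.nu_i if population == "i" else series.nu_e
        x = np.asarray(x, float)
        fs = series.fs
    else:
        x = np.asarray(series, float)
        if fs is None:
            raise ValueError("fs is required for plain arrays")
    if x.ndim == 2:
        x = x.mean(axis=0)
    nperseg = int(round(window_s * fs))
    if x.size < nperseg:
        raise ValueError(
            f"series too short for the {window_s}-s analysis window "
            f"({x.size / fs:.2f} s available)")
    f, P = signal.welch(x - x.mean(), fs=fs, nperseg=nperseg, window="hann",
                        noverlap=nperseg // 2)
    sel = (f >= f_range[0]) & (f <= f_range[1])
    peak = float(f[sel][np.argmax(P[sel])])
    return f, P, peak


def fc_pearson(series, population: str = "e") -> FCMatrix:
    """Pairwise Pearson correlation of regional rate series.

    Zero-variance series produce NaN rows/columns (flagged, excluded from
    ``offdiag`` summaries).
    """
    x, _ = (np.asarray(series.nu_i if population == "i" else series.nu_e,
                       float), None) if hasattr(series, "nu_e") \
        else (np.asarray(series, float), None)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 regions")
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, 1.0)
    return FCMatrix(values=r, metric="pearson", population=population)


def pli(series, population: str = "e", epoch_s: float = 1.0,
        fs: float = None) -> FCMatrix:
    """Phase-lag index per region pair, averaged over epochs.

    Per epoch, PLI_ij = |< sign(psi_i(t) - psi_j(t)) >_t| with psi the Hilbert
    phase of the mean-subtracted rate; the reported matrix is the mean over
    all complete epochs.  Identical signals (zero phase difference) give 0;
    a constant nonzero lag gives 1.  Constant series have undefined phase and
    yield NaN.
    """
    if hasattr(series, "nu_e"):
        x = np.asarray(series.nu_i if population == "i" else series.nu_e, float)
        fs = series.fs
    else:
        x = np.asarray(series, float)
        if fs is None:
            raise ValueError("fs is required for plain arrays")
    n, T = x.shape
    ep = int(round(epoch_s * fs))
    if ep < 2 or T < ep:
        raise ValueError("series shorter than one epoch")
    n_ep = T // ep
    flat = x.std(axis=1) == 0
    acc = np.zeros((n, n))
    for e in range(n_ep):
        seg = x[:, e * ep:(e + 1) * ep]
        seg = seg - seg.mean(axis=1, keepdims=True)
        psi = np.angle(signal.hilbert(seg, axis=1))
        dpsi = psi[:, None, :] - psi[None, :, :]
        acc += np.abs(np.mean(np.sign(np.sin(dpsi)), axis=-1))
    vals = acc / n_ep
    np.fill_diagonal(vals, 0.0)
    vals[flat, :] = np.nan
    vals[:, flat] = np.nan
    np.fill_diagonal(vals, 0.0)
    return FCMatrix(values=vals, metric="pli", population=population)


def distance_profile(fc: FCMatrix, distances: np.ndarray, n_bins: int = 5) -> dict:
    """Functional connectivity versus inter-region distance.

    Distances are cut into ``n_bins`` equal-width bins; empty bins are merged
    with their left neighbor (recorded in ``merged_bins``).  Returns per-bin
    values/means, a Kruskal-Wallis omnibus test across bins, Mann-Whitney U
    tests of the middle bin against every other bin, and the least-squares
    slope of FC vs distance.
    """
    d = np.asarray(distances, float)
    if d.shape != fc.values.shape:
        raise ValueError("distance matrix shape mismatch")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    iu = np.triu_indices(fc.n_regions, 1)
    dist = d[iu]
    vals = fc.values[iu]
    ok = np.isfinite(vals)
    dist, vals = dist[ok], vals[ok]

    edges = np.linspace(dist.min(), dist.max(), n_bins + 1)
    idx = np.clip(np.digitize(dist, edges[1:-1]), 0, n_bins - 1)
    groups = [vals[idx == i] for i in range(n_bins)]
    merged = []
    i = 1
    while i < len(groups):
        if groups[i].size == 0:
            merged.append(i)
            groups[i - 1] = np.concatenate([groups[i - 1], groups[i]])
            del groups[i]
        else:
            i += 1
    if groups and groups[0].size == 0:
        merged.append(0)
        groups[1] = np.concatenate([groups[0], groups[1]])
        del groups[0]

    centers = [0.5 * (edges[i] + edges[i + 1]) for i in range(n_bins)]
    kw_stat, kw_p = stats.kruskal(*groups) if len(groups) > 1 else (np.nan, np.nan)
    mid = len(groups) // 2
    mwu = {}
    for i, g in enumerate(groups):
        if i == mid:
            continue
        u, p = stats.mannwhitneyu(groups[mid], g, alternative="two-sided")
        mwu[i] = {"U": float(u), "p": float(p)}
    slope, intercept, r, p_slope, se = stats.linregress(dist, vals)
    return {
        "edges": edges,
        "centers": centers[:len(groups)],
        "bin_values": groups,
        "bin_means": np.array([g.mean() for g in groups]),
        "bin_medians": np.array([float(np.median(g)) for g in groups]),
        "merged_bins": merged,
        "kruskal": {"H": float(kw_stat), "p": float(kw_p)},
        "middle_bin": mid,
        "mannwhitney_mid_vs": mwu,
        "slope": float(slope),
        "slope_p": float(p_slope),
    }


def compare_populations(fc_e: FCMatrix, fc_i: FCMatrix) -> dict:
    """Independent t-test of excitatory vs inhibitory off-diagonal FC.

    Sign convention: t is computed for (excitatory - inhibitory), so stronger
    inhibitory coupling gives t < 0.  Returns t, p and the per-pair
    differences.
    """
    if fc_e.values.shape != fc_i.values.shape:
        raise ValueError("FC matrices must have matching shapes")
    iu = np.triu_indices(fc_e.n_regions, 1)
    xe, xi = fc_e.values[iu], fc_i.values[iu]
    ok = np.isfinite(xe) & np.isfinite(xi)
    xe, xi = xe[ok], xi[ok]
    t, p = stats.ttest_ind(xe, xi)
    return {"t": float(t), "p": float(p), "diff": xe - xi,
            "mean_e": float(xe.mean()), "mean_i": float(xi.mean())}
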