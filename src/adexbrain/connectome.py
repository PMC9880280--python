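"""Structural connectomes: loading, normalization, delays, null models, synthesis.

A connectome is a region-level weighted directed graph (weights C_jk for the
connection j -> k) with white-matter tract lengths that determine axonal
conduction delays, 3-D region centres, gray-matter volumes and hemisphere
tags.  The reader understands the TVB connectivity-zip dialect
(weights.txt / tract_lengths.txt / centres.txt) and plain CSV matrices.

Because the empirical reference dataset (a 68-region human parcellation from
diffusion tractography) requires a download, :func:`generate_synthetic`
produces a statistically similar stand-in — two mirrored hemispheres,
heavy-tailed distance-decaying weights — so every experiment can run
self-contained.
"""

from __future__ import annotations

import io
import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .params import rng_from_seed

__all__ = [
    "Connectome",
    "load_connectome",
    "normalize_weights",
    "compute_delays",
    "shuffle_weights",
    "generate_synthetic",
]

DEFAULT_AXONAL_SPEED = 3.0      # mm/ms; typical large-scale modeling default


@dataclass
class Connectome:
    """Region-level structural connectivity.

    weights[j, k] is the (dimensionless, nonnegative) strength of j -> k;
    the diagonal is ignored by the coupling, which treats C_kk = 1.
    tract_lengths are in mm and symmetric; centres in mm.
    """

    weights: np.ndarray
    tract_lengths: np.ndarray
    centres: np.ndarray
    labels: list = None
    volumes: Optional[np.ndarray] = None
    hemisphere: Optional[np.ndarray] = None     # 0 = left, 1 = right

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float)
        self.tract_lengths = np.asarray(self.tract_lengths, float)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n) or self.tract_lengths.shape != (n, n):
            raise ValueError("weights and tract_lengths must be square and matched")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(self.tract_lengths < 0):
            raise ValueError("tract lengths must be nonnegative")
        if not np.allclose(self.tract_lengths, self.tract_lengths.T):
            raise ValueError("tract lengths must be symmetric")
        self.centres = np.asarray(self.centres, float)
        if self.centres.shape != (n, 3) or not np.all(np.isfinite(self.centres)):
            raise ValueError("centres must be finite and of shape (n, 3)")
        if self.labels is None:
            self.labels = [f"region-{i:02d}" for i in range(n)]
        if self.volumes is not None:
            self.volumes = np.asarray(self.volumes, float)
        if self.hemisphere is None:
            # infer from label prefix, else from the sign of the x coordinate
            hemi = []
            for i, lab in enumerate(self.labels):
                low = str(lab).lower()
                if low.startswith(("lh", "left")) or "-lh-" in low or "_l_" in low:
                    hemi.append(0)
                elif low.startswith(("rh", "right")) or "-rh-" in low or "_r_" in low:
                    hemi.append(1)
                else:
                    hemi.append(int(self.centres[i, 0] > 0))
            self.hemisphere = np.array(hemi)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def euclidean_distances(self) -> np.ndarray:
        """Inter-centre Euclidean distance matrix (mm), used by the
        distance-profile analyses; delays use tract lengths instead."""
        d = self.centres[:, None, :] - self.centres[None, :, :]
        return np.sqrt((d ** 2).sum(-1))

    def region_index(self, target) -> int:
        """Resolve a region given an integer index or a (partial) label match."""
        if isinstance(target, (int, np.integer)):
            if not 0 <= target < self.n_regions:
                raise KeyError(f"region index {target} out of range")
            return int(target)
        needle = str(target).lower().replace(" ", "").replace("_", "").replace("-", "")
        hits = [i for i, lab in enumerate(self.labels)
                if needle in str(lab).lower().replace(" ", "").replace("_", "")
                .replace("-", "")]
        if not hits:
            raise KeyError(f"no region label matches {target!r}")
        return hits[0]

    def to_csv_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savetxt(path / "weights.csv", self.weights, delimiter=",")
        np.savetxt(path / "tract_lengths.csv", self.tract_lengths, delimiter=",")
        np.savetxt(path / "centres.csv", self.centres, delimiter=",")
        (path / "labels.txt").write_text("\n".join(map(str, self.labels)) + "\n")


def _parse_matrix(text: str, name: str) -> np.ndarray:
    rows = []
    width = None
    for ln, line in enumerate(text.strip().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        try:
            row = [float(x) for x in parts]
        except ValueError as e:
            raise ValueError(f"{name}: non-numeric entry on line {ln}") from e
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise ValueError(
                f"{name}: ragged matrix, line {ln} has {len(row)} columns "
                f"(expected {width})")
        rows.append(row)
    return np.array(rows)


def _parse_centres(text: str):
    """TVB centres.txt: 'label x y z' per row (label optional)."""
    labels, xyz = [], []
    for ln, line in enumerate(text.strip().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        try:
            coords = [float(x) for x in parts[-3:]]
        except ValueError as e:
            raise ValueError(f"centres: bad coordinates on line {ln}") from e
        xyz.append(coords)
        labels.append(" ".join(parts[:-3]) if len(parts) > 3 else f"region-{ln - 1:02d}")
    return labels, np.array(xyz)


def load_connectome(path, dialect: str = "auto") -> Connectome:
    """Read a connectome from a TVB connectivity zip or a directory of CSVs.

    The zip dialect expects weights.txt, tract_lengths.txt and centres.txt;
    the csv dialect expects weights.csv, tract_lengths.csv, centres.csv and
    optionally labels.txt in a directory.  A missing centres file yields a
    Connectome with NaN-free dummy centres and ``delays_available=False``
    semantics is avoided by requiring centres in both dialects.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "tvb-zip" if path.suffix == ".zip" else "csv"
    if dialect == "tvb-zip":
        with zipfile.ZipFile(path) as zf:
            names = {Path(n).name: n for n in zf.namelist()}

            def read(fname):
                if fname not in names:
                    raise FileNotFoundError(f"{fname} not found in {path}")
                return io.TextIOWrapper(zf.open(names[fname])).read()

            w = _parse_matrix(read("weights.txt"), "weights")
            tl = _parse_matrix(read("tract_lengths.txt"), "tract_lengths")
            labels, centres = _parse_centres(read("centres.txt"))
    elif dialect == "csv":
        w = _parse_matrix((path / "weights.csv").read_text(), "weights")
        tl = _parse_matrix((path / "tract_lengths.csv").read_text(), "tract_lengths")
        cen_file = path / "centres.csv"
        if cen_file.exists():
            centres = _parse_matrix(cen_file.read_text(), "centres")
            labels = None
        else:
            raise FileNotFoundError(f"centres.csv missing in {path}")
        lab_file = path / "labels.txt"
        if lab_file.exists():
            labels = lab_file.read_text().strip().splitlines()
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if w.shape != tl.shape or w.shape[0] != w.shape[1]:
        raise ValueError(
            f"shape mismatch: weights {w.shape} vs tract_lengths {tl.shape}")
    tl = 0.5 * (tl + tl.T)      # tolerate tiny asymmetries from text round-trips
    return Connectome(weights=w, tract_lengths=tl, centres=centres, labels=labels)


def normalize_weights(fiber_counts: np.ndarray, volumes: np.ndarray) -> np.ndarray:
    """Tractography fiber counts -> coupling weights.

    w_jk = f_jk / (vol_j + vol_k), then globally rescaled so max w = 1 (the
    global coupling strength S carries all magnitude).  All-zero input skips
    the rescale.
    """
    f = np.asarray(fiber_counts, float)
    vol = np.asarray(volumes, float)
    if np.any(vol <= 0):
        raise ValueError("volumes must be positive")
    w = f / (vol[:, None] + vol[None, :])
    m = w.max()
    if m > 0:
        w = w / m
    return w


def compute_delays(conn: Connectome, v_c: float = DEFAULT_AXONAL_SPEED) -> np.ndarray:
    """Axonal delays d_jk = tract_length_jk / v_c (ms), zero diagonal."""
    if v_c <= 0:
        raise ValueError("axonal speed must be positive")
    d = conn.tract_lengths / v_c
    np.fill_diagonal(d, 0.0)
    return d


def shuffle_weights(conn: Connectome, seed: int = 0) -> Connectome:
    """Connectome null model: successively permute each region's outgoing
    off-diagonal weights.  Tract lengths (hence delays) are untouched; every
    row keeps its weight multiset."""
    if conn.n_regions < 2:
        raise ValueError("need at least 2 regions")
    rng = rng_from_seed(seed, 2)
    w = conn.weights.copy()
    n = conn.n_regions
    for j in range(n):
        cols = np.array([k for k in range(n) if k != j])
        w[j, cols] = w[j, cols[rng.permutation(n - 1)]]
    return replace(conn, weights=w)


def generate_synthetic(n_regions: int = 68, seed: int = 0,
                       hemisphere_offset: float = 35.0,
                       semi_axes: tuple = (25.0, 45.0, 35.0),
                       tortuosity: float = 1.3,
                       decay_mm: float = 30.0,
                       inter_hemi_factor: float = 0.3,
                       sigma_lognormal: float = 2.0,
                       homotopic_weight: float = 8.0) -> Connectome:
    """Synthetic two-hemisphere connectome emulating tractography statistics.

    Region centres are sampled inside two mirrored ellipsoids (semi-axes in
    mm, mirrored about the x = 0 midplane); tract lengths are inter-centre
    Euclidean distances times a tortuosity factor; weights are log-normal
    (heavy-tailed), decay exponentially with distance, are denser within a
    hemisphere, symmetric, and rescaled to max 1.  Mirror-pair (homotopic)
    regions receive a strong callosal connection of relative strength
    ``homotopic_weight`` — a robust feature of human tractography that gives
    the graph its characteristic mid-range coupling scale.  Deterministic per
    seed.
    """
    if n_regions < 4:
        raise ValueError("need at least 4 regions")
    if n_regions % 2:
        raise ValueError("n_regions must be even (hemispheric split)")
    rng = rng_from_seed(seed, 3)
    half = n_regions // 2
    ax = np.asarray(semi_axes)
    pts = []
    while len(pts) < half:
        u = rng.uniform(-1, 1, size=3)
        if (u ** 2).sum() <= 1.0:
            pts.append(u * ax)
    left = np.array(pts)
    left[:, 0] = -np.abs(left[:, 0]) - hemisphere_offset / 2
    right = left.copy()
    right[:, 0] *= -1.0          # mirror through the midplane
    centres = np.vstack([left, right])

    d = centres[:, None, :] - centres[None, :, :]
    dist = np.sqrt((d ** 2).sum(-1))
    tl = dist * tortuosity
    np.fill_diagonal(tl, 0.0)

    logw = rng.normal(0.0, sigma_lognormal, size=(n_regions, n_regions))
    w = np.exp(logw) * np.exp(-dist / decay_mm)
    hemi = np.repeat([0, 1], half)
    inter = hemi[:, None] != hemi[None, :]
    w[inter] *= inter_hemi_factor
    w = 0.5 * (w + w.T)          # tractography weights are undirected
    np.fill_diagonal(w, 0.0)
    w /= w.max()
    for i in range(half):        # homotopic callosal connections
        w[i, i + half] += homotopic_weight
        w[i + half, i] += homotopic_weight
    w /= w.max()

    labels = ([f"lh-region-{i:02d}" for i in range(half - 1)] + ["lh-premotor"]
              + [f"rh-region-{i:02d}" for i in range(half - 1)] + ["rh-premotor"])
    volumes = np.exp(rng.normal(0.0, 0.3, size=n_regions))
    return Connectome(weights=w, tract_lengths=tl, centres=centres,
                      labels=labels, volumes=volumes, hemisphere=hemi)
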