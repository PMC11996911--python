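"""Alpha diversity, Bray-Curtis dissimilarity, PCoA, and beta-dispersion.

Alpha indices follow the mothur conventions (observed richness ``sobs``
and Shannon H' with natural log by default). Beta diversity is
abundance-based Bray-Curtis; ordination is classical PCoA (Gower
double-centering) with optional Lingoes/Cailliez corrections for
negative eigenvalues. PERMDISP computes per-sample distances to group
centroids in the full PCoA space, with the imaginary-axis correction
for negative eigenvalues, and a permutation F-test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import OrdinationResults, pcoa as _skbio_pcoa

from .io import CommunityTable, ValidationError


def sobs(sample_counts) -> int:
    """Observed richness: number of taxa with count > 0."""
    c = np.asarray(sample_counts)
    if np.any(c < 0):
        raise ValueError("negative counts")
    return int(np.count_nonzero(c))


def shannon(sample_counts, log_base: str | float = "e") -> float:
    """Shannon H' = -sum p_i log p_i over taxa with p_i > 0."""
    c = np.asarray(sample_counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative counts")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero sample has no Shannon index")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    if log_base == 2:
        h /= np.log(2)
    elif log_base != "e":
        raise ValueError(f"log_base must be 'e' or 2, got {log_base!r}")
    return h


def alpha_diversity(table: CommunityTable, log_base="e") -> pd.DataFrame:
    """Tidy per-sample table of sobs and Shannon."""
    rows = []
    for s in table.sample_ids:
        c = table.df.loc[s].to_numpy()
        rows.append({"sample_id": s, "sobs": sobs(c),
                     "shannon": shannon(c, log_base)})
    return pd.DataFrame(rows).set_index("sample_id")


def bray_curtis(table: CommunityTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis: BC(x,y) = sum|x_i - y_i| / sum(x_i + y_i)."""
    if table.shape[0] < 2:
        raise ValidationError("need at least 2 samples for a distance matrix")
    totals = table.sample_totals()
    if (totals == 0).any():
        zero = list(totals.index[totals == 0])
        raise ValidationError(f"zero-total samples: {zero}")
    d = pdist(table.counts.astype(float), metric="braycurtis")
    return DistanceMatrix(squareform(d), ids=table.sample_ids)


def pcoa(dm: DistanceMatrix, negative_eigen: str = "keep",
         dimensions: int | None = None) -> OrdinationResults:
    """Principal coordinates of a distance matrix.

    ``negative_eigen`` handles negative eigenvalues from semi-metric
    distances: ``keep`` reports raw eigenvalues with proportions over the
    positive part; ``lingoes`` / ``cailliez`` apply the standard additive
    corrections to the distances before decomposition.
    """
    if negative_eigen not in ("keep", "lingoes", "cailliez"):
        raise ValueError(f"unknown negative_eigen policy {negative_eigen!r}")
    if negative_eigen != "keep":
        dm = _correct_negative(dm, negative_eigen)
    res = _skbio_pcoa(dm, method="eigh", number_of_dimensions=dimensions or 0)
    return res


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _correct_negative(dm: DistanceMatrix, method: str) -> DistanceMatrix:
    d = dm.data
    g = _gower_center(d)
    eig = np.linalg.eigvalsh(g)
    if eig[0] >= -1e-12:
        return dm
    off = ~np.eye(d.shape[0], dtype=bool)
    d2 = d.copy()
    if method == "lingoes":
        c1 = -eig[0]
        d2[off] = np.sqrt(d[off] ** 2 + 2 * c1)
    else:  # cailliez
        n = d.shape[0]
        delta1 = g                             # J(-1/2 d^2)J
        delta2 = _gower_center_raw(-0.5 * d)   # J(-1/2 d)J
        block = np.block([[np.zeros((n, n)), 2.0 * delta1],
                          [-np.eye(n), -4.0 * delta2]])
        c2 = float(np.max(np.linalg.eigvals(block).real))
        d2[off] = d[off] + c2
    return DistanceMatrix(d2, ids=dm.ids)


def _gower_center_raw(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


# ---------------------------------------------------------------------------
# PERMDISP
# ---------------------------------------------------------------------------

def beta_dispersion(dm: DistanceMatrix, groups, permutations: int = 999,
                    seed: int = 0) -> dict:
    """Homogeneity of multivariate dispersion (PERMDISP, centroid-based).

    Embeds the samples by PCoA keeping all axes; distances to the group
    centroid subtract the squared distance on negative-eigenvalue
    ("imaginary") axes. Returns per-sample distances, the one-way F on
    those distances, and a permutation p-value from shuffling group
    labels.
    """
    groups = pd.Series(np.asarray(groups), index=list(dm.ids))
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise ValidationError("need at least 2 groups")
    if (sizes < 2).any():
        raise ValidationError(
            f"groups of size 1: {list(sizes.index[sizes < 2])}")

    g = _gower_center(dm.data)
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = np.abs(eigval) > 1e-10 * max(1.0, np.abs(eigval).max())
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    coords = eigvec * np.sqrt(np.abs(eigval))
    pos = eigval > 0

    dists = np.zeros(len(groups))
    for lab in sizes.index:
        m = (groups == lab).to_numpy()
        cen = coords[m].mean(axis=0)
        diff2 = (coords[m] - cen) ** 2
        d2 = diff2[:, pos].sum(axis=1) - diff2[:, ~pos].sum(axis=1)
        dists[m] = np.sqrt(np.maximum(d2, 0.0))

    labels = groups.to_numpy()
    f_obs = _anova_f(dists, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        f_p = _anova_f(dists, rng.permutation(labels))
        if f_p >= f_obs:
            hits += 1
    p = (hits + 1) / (permutations + 1)
    return {"distances": pd.Series(dists, index=list(dm.ids)),
            "F": f_obs, "p_value": p, "permutations": permutations}


def _anova_f(values: np.ndarray, labels: np.ndarray) -> float:
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    labs, inv = np.unique(labels, return_inverse=True)
    for k in range(len(labs)):
        v = values[inv == k]
        ss_between += len(v) * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
    df_b = len(labs) - 1
    df_w = len(values) - len(labs)
    if ss_within == 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / df_b) / (ss_within / df_w)
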