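"""Phylogenetic and compositional null models for community assembly.

The inference chain follows the Stegen-style framework for partitioning
assembly processes:

1. betaMNTD — abundance-weighted mean distance from each taxon in one
   community to its nearest phylogenetic neighbour in the other.
2. betaNTI — the z-score of observed betaMNTD against a null built by
   shuffling tip labels across the whole tree ("taxa shuffle").
   |betaNTI| >= 2 signals selection (deterministic assembly); the sign
   separates heterogeneous/variable (+) from homogeneous (-) selection.
3. RC-Bray — Raup-Crick on Bray-Curtis against a null that reassembles
   each community preserving its observed richness, drawing species with
   probability proportional to occurrence frequency and filling
   abundance proportional to regional relative abundance. Rescaled to
   [-1, 1]; beyond +/-0.95 signals dispersal limitation / homogenizing
   dispersal for pairs not already attributed to selection.
4. Remaining pairs are attributed to ecological drift.

All randomness flows from a single seed; results are independent of the
order in which sample pairs are enumerated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from .io import CommunityTable, ValidationError

logger = logging.getLogger("ecoassembly")

PROCESSES = ("heterogeneous_selection", "homogeneous_selection",
             "dispersal_limitation", "homogenizing_dispersal", "drift")

#: selection if |betaNTI| >= 2 (closed bound); RC thresholds are strict
BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


def cophenetic_matrix(tree: TreeNode, otu_ids) -> np.ndarray:
    """Tip-to-tip patristic distances, ordered as ``otu_ids``."""
    dm = tree.tip_tip_distances(list(otu_ids))
    # skbio preserves the requested id order
    return dm.filter(list(otu_ids)).data


def _weights(counts: np.ndarray, abundance_weighted: bool) -> np.ndarray:
    """Per-sample taxon weights: relative abundance, or uniform over
    present taxa for the unweighted variant."""
    w = counts.astype(float)
    if not abundance_weighted:
        w = (w > 0).astype(float)
    totals = w.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValidationError("sample with no tree-matched OTUs")
    return w / totals


def _beta_mntd_from_coph(coph: np.ndarray, weights: np.ndarray,
                         presence: np.ndarray) -> np.ndarray:
    """All-pairs betaMNTD given a cophenetic matrix.

    For each sample b, dmin[:, b] holds every taxon's distance to its
    nearest taxon present in b (zero for taxa present in b themselves,
    since d[i,i] = 0). Then
    betaMNTD[a, b] = 0.5 * (sum_i w[a,i] dmin[i,b] + sum_j w[b,j] dmin[j,a]),
    which is 0.5 * (P + P.T) with P = W @ dmin.
    """
    n, s = weights.shape
    dmin = np.empty((s, n))
    for b in range(n):
        cols = presence[b]
        dmin[:, b] = coph[:, cols].min(axis=1)
    p = weights @ dmin
    return 0.5 * (p + p.T)


def beta_mntd(table: CommunityTable, tree: TreeNode,
              abundance_weighted: bool = True) -> DistanceMatrix:
    """Observed beta mean nearest taxon distance between all sample pairs."""
    coph = cophenetic_matrix(tree, table.otu_ids)
    counts = table.counts
    w = _weights(counts, abundance_weighted)
    presence = counts > 0
    m = _beta_mntd_from_coph(coph, w, presence)
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(0.5 * (m + m.T), ids=table.sample_ids)


def beta_nti(table: CommunityTable, tree: TreeNode, reps: int = 999,
             seed: int = 0, abundance_weighted: bool = True,
             null_model: str = "taxa_shuffle") -> pd.DataFrame:
    """betaNTI z-scores for all sample pairs.

    Each null replicate permutes tip labels across the whole supplied
    tree (equivalently permutes rows/columns of the cophenetic matrix
    over all tips, observed or not) and rescores every pair, keeping
    abundances fixed. Shuffling over the full tree rather than only the
    observed taxa is what gives the test power against communities
    confined to a clade of a larger regional phylogeny. A degenerate
    phylogeny with zero null spread yields NaN with a warning.

    Returns a symmetric DataFrame of z-scores indexed by sample id.
    """
    if null_model != "taxa_shuffle":
        raise ValueError(f"unknown null model {null_model!r}")
    if reps < 100:
        raise ValueError("reps must be >= 100")
    otus = table.otu_ids
    tip_names = [t.name for t in tree.tips()]
    missing = set(otus) - set(tip_names)
    if missing:
        raise ValidationError(f"table OTUs absent from tree: "
                              f"{sorted(missing)[:5]}...")
    # canonical (sorted) taxon order so null draws do not depend on the
    # table's column order
    all_tips = sorted(tip_names)
    col = {name: k for k, name in enumerate(all_tips)}
    coph = cophenetic_matrix(tree, all_tips)
    counts = np.zeros((table.shape[0], len(all_tips)), dtype=np.int64)
    counts[:, [col[o] for o in otus]] = table.counts
    w = _weights(counts, abundance_weighted)
    presence = counts > 0
    n = counts.shape[0]
    iu = np.triu_indices(n, k=1)

    obs = _beta_mntd_from_coph(coph, w, presence)[iu]
    rng = np.random.default_rng(seed)
    nulls = np.empty((reps, len(obs)))
    s = coph.shape[0]
    for r in range(reps):
        perm = rng.permutation(s)
        nulls[r] = _beta_mntd_from_coph(coph[np.ix_(perm, perm)],
                                        w, presence)[iu]
    mu = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (obs - mu) / sd, np.nan)
    if np.isnan(z).any():
        logger.warning("beta_nti: %d pair(s) with zero null spread -> NaN",
                       int(np.isnan(z).sum()))
    out = np.zeros((n, n))
    out[iu] = z
    out += out.T
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=table.sample_ids, columns=table.sample_ids)


# ---------------------------------------------------------------------------
# RC-Bray
# ---------------------------------------------------------------------------

def _null_sample(rng: np.random.Generator, richness: int, total: int,
                 occ_p: np.ndarray, abund_p: np.ndarray,
                 n_otus: int) -> np.ndarray:
    """One null community: choose ``richness`` species by occurrence
    frequency without replacement, give each one individual, then fill
    the remaining ``total - richness`` individuals multinomially by
    regional relative abundance among the chosen species."""
    chosen = rng.choice(n_otus, size=richness, replace=False, p=occ_p)
    out = np.zeros(n_otus, dtype=np.int64)
    out[chosen] = 1
    remaining = total - richness
    if remaining > 0:
        p = abund_p[chosen]
        psum = p.sum()
        if psum == 0:
            p = np.full(richness, 1.0 / richness)
        else:
            p = p / psum
        out[chosen] += rng.multinomial(remaining, p)
    return out


def rc_bray(table: CommunityTable, reps: int = 999, seed: int = 0) -> pd.DataFrame:
    """Raup-Crick on Bray-Curtis, rescaled to [-1, 1].

    RC = 2 * ( (#{null BC < obs BC} + 0.5 * #{null BC = obs BC}) / reps - 0.5 ).
    Equality uses exact float comparison on identically computed
    Bray-Curtis values; ties are real when null draws coincide.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    counts = table.counts
    n, s = counts.shape
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    if np.any(richness == 0):
        raise ValidationError("zero-richness sample")
    if np.any(richness > s):
        raise ValidationError("sample richness exceeds pool size")
    occ = (counts > 0).sum(axis=0).astype(float)
    occ_p = occ / occ.sum()
    abund_p = counts.sum(axis=0).astype(float)
    abund_p = abund_p / abund_p.sum()
    # species never observed cannot be drawn (occurrence weight zero);
    # restrict the pool so choice() without replacement stays feasible
    pool = np.flatnonzero(occ > 0)
    if np.any(richness > len(pool)):
        raise ValidationError("sample richness exceeds occupied pool size")

    obs_bc = pdist(counts.astype(float), metric="braycurtis")
    rng = np.random.default_rng(seed)
    occ_pool = occ_p[pool] / occ_p[pool].sum()
    less = np.zeros(len(obs_bc))
    equal = np.zeros(len(obs_bc))
    null = np.empty((n, s))
    for _ in range(reps):
        for i in range(n):
            comm = np.zeros(s, dtype=np.int64)
            sub = _null_sample(rng, int(richness[i]), int(totals[i]),
                               occ_pool, abund_p[pool], len(pool))
            comm[pool] = sub
            null[i] = comm
        null_bc = pdist(null, metric="braycurtis")
        less += null_bc < obs_bc
        equal += null_bc == obs_bc
    rc = 2.0 * ((less + 0.5 * equal) / reps - 0.5)
    out = squareform(rc)
    return pd.DataFrame(out, index=table.sample_ids, columns=table.sample_ids)


# ---------------------------------------------------------------------------
# classification and partition
# ---------------------------------------------------------------------------

def classify_pair(beta_nti: float, rc_bray: float) -> str:
    """Assign one of the five assembly processes to a sample pair.

    Selection whenever |betaNTI| >= 2 (sign: + heterogeneous,
    - homogeneous), regardless of RC. Otherwise RC > 0.95 dispersal
    limitation, RC < -0.95 homogenizing dispersal, else drift. NaN
    betaNTI yields ``"undetermined"``.
    """
    if np.isnan(beta_nti):
        return "undetermined"
    if beta_nti >= BNTI_THRESHOLD:
        return "heterogeneous_selection"
    if beta_nti <= -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if rc_bray > RC_THRESHOLD:
        return "dispersal_limitation"
    if rc_bray < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    return "drift"


@dataclass
class AssemblyResult:
    """Pairwise null-model results plus per-group process fractions."""
    pairs: pd.DataFrame
    partition: pd.DataFrame


def classify_pairs(bmntd: DistanceMatrix, bnti: pd.DataFrame,
                   rc: pd.DataFrame,
                   pair_index: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Long-format pairwise table (i, j, beta_mntd, beta_nti, rc_bray, process)."""
    ids = list(bnti.index)
    if pair_index is None:
        pair_index = list(combinations(ids, 2))
    rows = []
    bm = bmntd.to_data_frame() if bmntd is not None else None
    for i, j in pair_index:
        z = float(bnti.loc[i, j])
        r = float(rc.loc[i, j])
        rows.append({
            "sample_i": i, "sample_j": j,
            "beta_mntd": float(bm.loc[i, j]) if bm is not None else np.nan,
            "beta_nti": z, "rc_bray": r,
            "process": classify_pair(z, r)})
    return pd.DataFrame(rows)


def partition_processes(pairs: pd.DataFrame, groups: pd.Series | None = None
                        ) -> pd.DataFrame:
    """Fraction of within-group pairs assigned to each process.

    ``groups`` maps sample id -> label; pairs whose two samples carry
    different labels are excluded (cross-group pairs are never pooled).
    Undetermined pairs are dropped with a logged count.
    """
    df = pairs.copy()
    if groups is not None:
        groups = pd.Series(groups)
        gi = df["sample_i"].map(groups)
        gj = df["sample_j"].map(groups)
        df = df[gi.eq(gj).fillna(False)]
        df = df.assign(group=gi[df.index])
    else:
        df = df.assign(group="all")
    n_undet = int((df["process"] == "undetermined").sum())
    if n_undet:
        logger.warning("partition_processes: excluding %d undetermined "
                       "pair(s)", n_undet)
    df = df[df["process"] != "undetermined"]
    rows = []
    for lab, sub in df.groupby("group", sort=True):
        if len(sub) == 0:
            logger.warning("partition_processes: group %r has no pairs", lab)
            continue
        frac = sub["process"].value_counts(normalize=True)
        row = {"group": lab, "n_pairs": len(sub)}
        for p in PROCESSES:
            row[p] = float(frac.get(p, 0.0))
        rows.append(row)
    return pd.DataFrame(rows)


def assembly_analysis(table: CommunityTable, tree: TreeNode,
                      groups: pd.Series | None = None, reps: int = 999,
                      seed: int = 0, abundance_weighted: bool = True
                      ) -> AssemblyResult:
    """Full chain: betaMNTD -> betaNTI, RC-Bray, classification, partition.

    The null models always treat the whole table as the regional
    metacommunity (occurrence frequencies and regional abundances come
    from all samples). When ``groups`` is given, only within-group pairs
    are classified and partitioned; cross-group pairs are never pooled.
    """
    rng = np.random.default_rng(seed)
    s1, s2 = (int(v) for v in rng.integers(0, 2**31 - 1, size=2))
    table = table.drop_empty_otus()
    bm = beta_mntd(table, tree, abundance_weighted)
    bn = beta_nti(table, tree, reps=reps, seed=s1,
                  abundance_weighted=abundance_weighted)
    rc = rc_bray(table, reps=reps, seed=s2)

    if groups is None:
        pair_index = None
    else:
        groups = pd.Series(groups)
        pair_index = [(i, j) for i, j in combinations(table.sample_ids, 2)
                      if groups.get(i) is not None
                      and groups.get(i) == groups.get(j)]
    pairs = classify_pairs(bm, bn, rc, pair_index=pair_index)
    part = partition_processes(pairs, groups=groups)
    return AssemblyResult(pairs=pairs, partition=part)
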