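"""Permutation-based community-factor statistics.

PERMANOVA (one- and two-factor crossed with interaction) follows the
McArdle & Anderson direct distance-matrix decomposition: with G the
Gower-centered matrix of the dissimilarities and H the hat matrix of a
design-matrix term, SS(term) = tr(H G) sequentially, pseudo-F compares
the term mean square to the residual mean square, and p-values come
from permuting raw sample labels. ANOSIM and Mantel are delegated to
scikit-bio; Procrustes/PROTEST, db-RDA variance partitioning,
ordination regression, rank tests and the Spearman heatmap are
implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as _skbio_anosim, mantel as _skbio_mantel
from skbio.stats.ordination import OrdinationResults

from .diversity import _gower_center, bray_curtis
from .io import CommunityTable, ValidationError

logger = logging.getLogger("ecoassembly")


@dataclass
class PermutationTestResult:
    statistic_name: str
    statistic: float
    p_value: float
    permutations: int
    seed: int | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _dummy(labels: np.ndarray) -> np.ndarray:
    """Full-rank treatment-coded dummy matrix (first level dropped)."""
    levels = pd.unique(labels)
    return np.column_stack([(labels == lv).astype(float)
                            for lv in levels[1:]]) \
        if len(levels) > 1 else np.empty((len(labels), 0))


def _hat(x: np.ndarray) -> np.ndarray:
    """Projection matrix onto the column space of [1, x]."""
    n = x.shape[0]
    xx = np.column_stack([np.ones(n), x])
    return xx @ np.linalg.pinv(xx)


def _cumulative_hats(n: int, terms: list[np.ndarray]) -> list[np.ndarray]:
    """Projection matrices for the nested design expansions [1], [1,X1],
    [1,X1,X2], ... (hat matrices do not change under permutation of G,
    so they are computed once)."""
    hats = [_hat(np.empty((n, 0)))]
    x = np.empty((n, 0))
    for t in terms:
        x = np.column_stack([x, t])
        hats.append(_hat(x))
    return hats


def _permanova_ss(g: np.ndarray, hats: list[np.ndarray]) -> np.ndarray:
    """Sequential (Type I) sums of squares: SS_k = tr(H_k G) - tr(H_{k-1} G)."""
    traces = np.array([np.sum(h * g.T) for h in hats])
    return np.diff(traces)


def permanova(dm: DistanceMatrix, metadata: pd.DataFrame,
              factors: list[str] | str, permutations: int = 999,
              seed: int = 0, interaction: bool = True) -> pd.DataFrame:
    """Permutational multivariate ANOVA on a distance matrix.

    One factor gives Anderson's one-way pseudo-F; two factors give a
    crossed design with an optional interaction term, sequential SS, and
    permutation of raw sample labels. Returns a table with one row per
    term plus the residual (df, SS, R2, pseudo-F, p).
    """
    if isinstance(factors, str):
        factors = [factors]
    if not 1 <= len(factors) <= 2:
        raise ValueError("one or two factors supported")
    ids = list(dm.ids)
    md = metadata.loc[ids]
    labels = [md[f].to_numpy() for f in factors]
    for f, lab in zip(factors, labels):
        sizes = pd.Series(lab).value_counts()
        if (sizes < 2).any():
            raise ValidationError(
                f"factor {f!r} has singleton level(s): "
                f"{list(sizes.index[sizes < 2])}")

    g = _gower_center(dm.data)
    n = len(ids)
    ss_total = float(np.trace(g))

    def build_terms(labs):
        terms, names, dfs = [], [], []
        for f, lab in zip(factors, labs):
            x = _dummy(lab)
            terms.append(x)
            names.append(f)
            dfs.append(x.shape[1])
        if len(labs) == 2 and interaction:
            combo = np.char.add(np.char.add(labs[0].astype(str), "::"),
                                labs[1].astype(str))
            full = _dummy(combo)
            # interaction df = full crossed df minus main-effect dfs
            terms.append(full)
            names.append(f"{factors[0]}:{factors[1]}")
            dfs.append(full.shape[1] - sum(dfs))
        return terms, names, dfs

    terms, names, dfs = build_terms(labels)
    hats = _cumulative_hats(n, terms)
    ss = _permanova_ss(g, hats)
    df_model = sum(dfs)
    df_resid = n - df_model - 1
    ss_resid = ss_total - ss.sum()
    ms_resid = ss_resid / df_resid
    f_obs = np.array([(ss[k] / dfs[k]) / ms_resid if dfs[k] > 0 else np.nan
                      for k in range(len(ss))])

    rng = np.random.default_rng(seed)
    hits = np.zeros(len(ss))
    for _ in range(permutations):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p = _permanova_ss(gp, hats)
        ss_resid_p = ss_total - ss_p.sum()
        ms_resid_p = ss_resid_p / df_resid
        f_p = np.array([(ss_p[k] / dfs[k]) / ms_resid_p if dfs[k] > 0
                        else np.nan for k in range(len(ss_p))])
        hits += f_p >= f_obs
    p = (hits + 1) / (permutations + 1)

    rows = []
    for k, name in enumerate(names):
        rows.append({"term": name, "df": dfs[k], "SS": ss[k],
                     "R2": ss[k] / ss_total, "pseudo_F": f_obs[k],
                     "p_value": p[k]})
    rows.append({"term": "Residual", "df": df_resid, "SS": ss_resid,
                 "R2": ss_resid / ss_total, "pseudo_F": np.nan,
                 "p_value": np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ANOSIM / Mantel (scikit-bio backed)
# ---------------------------------------------------------------------------

def anosim(dm: DistanceMatrix, groups, permutations: int = 999,
           seed: int = 0) -> PermutationTestResult:
    """ANOSIM rank statistic R in [-1, 1] with permutation p."""
    grouping = pd.Series(np.asarray(groups), index=list(dm.ids))
    sizes = grouping.value_counts()
    if len(sizes) < 2 or (sizes < 2).any():
        raise ValidationError("ANOSIM needs >= 2 groups of >= 2 samples")
    if np.allclose(dm.condensed_form(), dm.condensed_form()[0]):
        logger.warning("anosim: all distances tied; R = 0")
        return PermutationTestResult("ANOSIM R", 0.0, 1.0, permutations, seed)
    res = _skbio_anosim(dm, grouping.to_frame("g"), column="g",
                        permutations=permutations, seed=seed)
    return PermutationTestResult("ANOSIM R", float(res["test statistic"]),
                                 float(res["p-value"]), permutations, seed)


def mantel(dm_a: DistanceMatrix, dm_b: DistanceMatrix,
           method: str = "pearson", permutations: int = 999,
           seed: int = 0) -> PermutationTestResult:
    """Mantel correlation between two distance matrices."""
    for dm in (dm_a, dm_b):
        if np.allclose(dm.condensed_form(), dm.condensed_form()[0]):
            raise ValidationError("constant distance matrix: Mantel r "
                                  "undefined")
    r, p, n = _skbio_mantel(dm_a, dm_b, method=method,
                            permutations=permutations, seed=seed)
    return PermutationTestResult(f"Mantel r ({method})", float(r), float(p),
                                 permutations, seed, extras={"n": n})


def pca_ordination(data: pd.DataFrame, n_axes: int | None = None
                   ) -> OrdinationResults:
    """Principal components of a (samples x variables) table.

    Variables are z-scored first; used as the environmental-side
    configuration for Procrustes comparisons against community PCoA.
    """
    x = data.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        keep = sd > 0
        x = x[:, keep]
        sd = sd[keep]
    x = (x - x.mean(axis=0)) / sd
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = n_axes or len(s)
    scores = u[:, :k] * s[:k]
    eig = (s ** 2) / max(len(x) - 1, 1)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return OrdinationResults(
        "PCA", "Principal Component Analysis",
        eigvals=pd.Series(eig[:k], index=cols),
        samples=pd.DataFrame(scores, index=data.index, columns=cols),
        proportion_explained=pd.Series(eig[:k] / eig.sum(), index=cols))


# ---------------------------------------------------------------------------
# Procrustes / PROTEST
# ---------------------------------------------------------------------------

def _configuration(ord_or_array, ids=None) -> tuple[np.ndarray, list]:
    if isinstance(ord_or_array, OrdinationResults):
        df = ord_or_array.samples
        return df.to_numpy(dtype=float), list(df.index)
    arr = np.asarray(ord_or_array, dtype=float)
    return arr, list(ids) if ids is not None else list(range(len(arr)))


def _normalize_config(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0)
    norm = np.sqrt((x ** 2).sum())
    if norm == 0:
        raise ValidationError("degenerate (single-point) configuration")
    return x / norm


def _procrustes_m2(x: np.ndarray, y: np.ndarray) -> float:
    """Residual m^2 after optimal rotation+scaling of y onto x, both
    centered and scaled to unit sum of squares: m^2 = 1 - (sum sv)^2."""
    sv = np.linalg.svd(x.T @ y, compute_uv=False)
    return float(max(0.0, 1.0 - sv.sum() ** 2))


def procrustes(ord_a, ord_b, permutations: int = 999,
               seed: int = 0) -> PermutationTestResult:
    """Symmetric Procrustes superimposition with a PROTEST permutation test.

    Both configurations are centered and scaled to unit trace; the
    optimal orthogonal rotation and scaling of B onto A leaves residual
    M2, with correlation R = sqrt(1 - M2). The p-value permutes the rows
    of B.
    """
    xa, ids_a = _configuration(ord_a)
    xb, ids_b = _configuration(ord_b)
    if ids_a != ids_b:
        order = {s: k for k, s in enumerate(ids_b)}
        if set(ids_a) != set(ids_b):
            raise ValidationError("Procrustes inputs must share samples")
        xb = xb[[order[s] for s in ids_a]]
    # pad to common axis count
    k = max(xa.shape[1], xb.shape[1])
    xa = np.pad(xa, ((0, 0), (0, k - xa.shape[1])))
    xb = np.pad(xb, ((0, 0), (0, k - xb.shape[1])))
    xa = _normalize_config(xa)
    xb = _normalize_config(xb)
    m2 = _procrustes_m2(xa, xb)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        m2_p = _procrustes_m2(xa, xb[rng.permutation(len(xb))])
        if m2_p <= m2:
            hits += 1
    p = (hits + 1) / (permutations + 1)
    return PermutationTestResult(
        "Procrustes M2", m2, p, permutations, seed,
        extras={"correlation": float(np.sqrt(max(0.0, 1.0 - m2)))})


# ---------------------------------------------------------------------------
# variance partitioning (db-RDA)
# ---------------------------------------------------------------------------

@dataclass
class VpaResult:
    """Adjusted-R2 variance partition over named explanatory blocks."""
    blocks: list[str]
    #: adjusted R2 of every non-empty block union, keyed by frozenset
    combined: dict
    #: inclusion-exclusion fractions keyed by frozenset of block names
    #: (singletons are the unique fractions)
    fractions: dict
    residual: float


def _dbrda_r2(g: np.ndarray, x: np.ndarray) -> tuple[float, int]:
    """Raw db-RDA R2 = tr(H G)/tr(G) and the predictor rank."""
    xc = x - x.mean(axis=0)
    rank = np.linalg.matrix_rank(xc)
    h = _hat(xc)
    return float(np.trace(h @ g) / np.trace(g)), rank


def _adjust_r2(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        raise ValidationError("more predictors than residual df; reduce "
                              "variables")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def vpa(data, blocks: dict[str, pd.DataFrame]) -> VpaResult:
    """Variance partitioning of community variation among variable blocks.

    ``data`` is a CommunityTable (Bray-Curtis is computed) or a
    DistanceMatrix. Each block is standardized (z-score) and fitted by
    db-RDA; adjusted R2 (Ezekiel) of every block union is decomposed by
    inclusion-exclusion into unique and shared fractions. Small negative
    unique fractions are an expected adjusted-R2 artifact and are
    reported as-is.
    """
    if len(blocks) < 2:
        raise ValueError("need at least 2 blocks")
    if isinstance(data, CommunityTable):
        dm = bray_curtis(data)
    else:
        dm = data
    ids = list(dm.ids)
    n = len(ids)
    g = _gower_center(dm.data)

    z = {}
    for name, df in blocks.items():
        x = df.loc[ids].to_numpy(dtype=float)
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValidationError(f"constant variable in block {name!r}")
        z[name] = (x - x.mean(axis=0)) / sd
        if x.shape[1] >= n:
            raise ValidationError(
                f"block {name!r} has >= n variables; reduce variables")

    names = list(blocks)
    combined: dict = {}
    for r in range(1, len(names) + 1):
        for sub in combinations(names, r):
            x = np.column_stack([z[b] for b in sub])
            r2, rank = _dbrda_r2(g, x)
            combined[frozenset(sub)] = _adjust_r2(r2, n, rank)

    # fraction attributable to exactly the blocks in `key`
    # (singleton keys are the unique fractions):
    # f(T) = sum_{S subset T} (-1)^(|S|+1) adjR2((U \ T) union S)
    fractions: dict = {}
    full = frozenset(names)
    for r in range(1, len(names) + 1):
        for sub in combinations(names, r):
            key = frozenset(sub)
            others = full - key
            val = 0.0
            for r2_ in range(0, len(key) + 1):
                for inner in combinations(sorted(key), r2_):
                    u = others | frozenset(inner)
                    if u:
                        val += (-1) ** (len(inner) + 1) * combined[u]
            fractions[key] = val
    residual = 1.0 - combined[full]
    return VpaResult(blocks=names, combined=combined,
                     fractions=fractions, residual=residual)


# ---------------------------------------------------------------------------
# ordination regression, rank tests, Spearman heatmap
# ---------------------------------------------------------------------------

def ordination_regression(ordination: OrdinationResults, soil: pd.DataFrame,
                          axis: int = 1) -> pd.DataFrame:
    """OLS of one ordination axis on each environmental variable.

    Returns a table ranked by R2 identifying the top drivers of the
    axis; constant variables are skipped with a warning.
    """
    scores = ordination.samples.iloc[:, axis - 1]
    soil = soil.loc[scores.index]
    rows = []
    for var in soil.columns:
        x = soil[var].to_numpy(dtype=float)
        if not np.isfinite(x).all():
            raise ValidationError(f"non-finite values in {var!r}")
        if np.ptp(x) == 0:
            logger.warning("ordination_regression: %r is constant; skipped",
                           var)
            continue
        res = sps.linregress(x, scores.to_numpy())
        rows.append({"variable": var, "slope": res.slope,
                     "intercept": res.intercept,
                     "R2": res.rvalue ** 2, "p_value": res.pvalue})
    out = pd.DataFrame(rows).sort_values("R2", ascending=False)
    return out.reset_index(drop=True)


def group_difference_tests(values: pd.DataFrame | pd.Series, groups,
                           test: str = "wilcoxon_ranksum",
                           mtc: str = "none") -> pd.DataFrame:
    """Rank-based group tests per feature with optional BH correction.

    ``values`` holds features as columns (a Series is one feature);
    Wilcoxon rank-sum uses the exact distribution for <= 10 observations
    per group, the tie-corrected normal approximation otherwise;
    Kruskal-Wallis uses the tie-corrected chi-square approximation.
    """
    if isinstance(values, pd.Series):
        values = values.to_frame(values.name or "value")
    groups = pd.Series(np.asarray(groups), index=values.index)
    labs = pd.unique(groups)
    sizes = groups.value_counts()
    if (sizes < 2).any():
        raise ValidationError("each group needs >= 2 observations")
    rows = []
    for feat in values.columns:
        v = values[feat]
        samples = [v[groups == lab].to_numpy(dtype=float) for lab in labs]
        if np.ptp(np.concatenate(samples)) == 0:
            rows.append({"feature": feat, "stat": 0.0, "p_value": 1.0})
            continue
        if test == "wilcoxon_ranksum":
            if len(labs) != 2:
                raise ValueError("wilcoxon_ranksum needs exactly 2 groups")
            method = ("exact" if max(len(s) for s in samples) <= 10
                      else "asymptotic")
            res = sps.mannwhitneyu(samples[0], samples[1],
                                   alternative="two-sided", method=method)
        elif test == "kruskal_wallis":
            res = sps.kruskal(*samples)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append({"feature": feat, "stat": float(res.statistic),
                     "p_value": float(res.pvalue)})
    out = pd.DataFrame(rows)
    if mtc == "BH":
        out["q_value"] = sps.false_discovery_control(out["p_value"],
                                                     method="bh")
    elif mtc != "none":
        raise ValueError(f"unknown mtc {mtc!r}")
    return out


def spearman_heatmap(taxa: pd.DataFrame, soil: pd.DataFrame,
                     mtc: str = "BH") -> pd.DataFrame:
    """Spearman rho between each taxon and each environmental variable.

    Returns a long table (taxon, variable, rho, p, q) with BH applied
    across all cells; constant vectors yield NA cells.
    """
    if len(taxa) < 4:
        raise ValidationError("need >= 4 samples for Spearman correlations")
    soil = soil.loc[taxa.index]
    rows = []
    for t in taxa.columns:
        for v in soil.columns:
            a = taxa[t].to_numpy(dtype=float)
            b = soil[v].to_numpy(dtype=float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                rows.append({"taxon": t, "variable": v,
                             "rho": np.nan, "p_value": np.nan})
                continue
            rho, p = sps.spearmanr(a, b)
            rows.append({"taxon": t, "variable": v,
                         "rho": float(rho), "p_value": float(p)})
    out = pd.DataFrame(rows)
    if mtc == "BH":
        mask = out["p_value"].notna()
        q = np.full(len(out), np.nan)
        if mask.any():
            q[mask.to_numpy()] = sps.false_discovery_control(
                out.loc[mask, "p_value"], method="bh")
        out["q_value"] = q
    return out
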