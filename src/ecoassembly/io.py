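"""Core containers and file I/O for the pipeline.

The central object is :class:`CommunityTable`, a validated samples x OTUs
count matrix. Trees are `skbio.TreeNode` objects read from Newick; sample
metadata and soil-property tables are plain pandas DataFrames indexed by
sample id and validated on read.
"""

from __future__ import annotations

import io as _io
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("ecoassembly")

COMPARTMENTS = ("rhizosphere", "endosphere")
HABITATS = ("mountain", "plain", "saline-alkali")

#: soil columns that are physically non-negative (concentrations, enzyme
#: activities, moisture, precipitation). MAT and altitude may be negative.
_NONNEG_SOIL = {"TN", "TP", "AN", "AP", "AK", "OC", "C/N", "EC",
                "ALP", "SUC", "UR", "SM", "MAP"}


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = sorted(ids[ids.duplicated()].unique().tolist())
        raise ValidationError(f"duplicate {what}: {dups}")


class CommunityTable:
    """Samples x OTUs non-negative integer count matrix.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows are samples, columns OTUs; values are non-negative integers.
    """

    def __init__(self, counts: pd.DataFrame):
        if not isinstance(counts, pd.DataFrame):
            counts = pd.DataFrame(counts)
        _check_unique(counts.index, "sample ids")
        _check_unique(counts.columns, "OTU ids")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = np.argwhere(~np.vectorize(np.isreal)(arr))
            r, c = bad[0]
            raise ValidationError(
                f"non-numeric count at sample {counts.index[r]!r}, "
                f"OTU {counts.columns[c]!r}")
        if np.any(arr < 0):
            r, c = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at sample {counts.index[r]!r}, "
                f"OTU {counts.columns[c]!r}")
        if not np.allclose(arr, np.round(arr)):
            r, c = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise ValidationError(
                f"non-integer count at sample {counts.index[r]!r}, "
                f"OTU {counts.columns[c]!r}")
        self.df = counts.astype(np.int64)

    # -- basic views ------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def sample_totals(self) -> pd.Series:
        return self.df.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample proportions; errors on zero-total samples."""
        totals = self.sample_totals()
        if (totals == 0).any():
            zero = list(totals.index[totals == 0])
            raise ValidationError(f"zero-total samples: {zero}")
        return self.df.div(totals, axis=0)

    def subset(self, samples=None, otus=None) -> "CommunityTable":
        df = self.df
        if samples is not None:
            df = df.loc[list(samples)]
        if otus is not None:
            df = df[list(otus)]
        return CommunityTable(df)

    def drop_empty_otus(self) -> "CommunityTable":
        keep = self.df.columns[self.df.sum(axis=0) > 0]
        return CommunityTable(self.df[keep])

    def __eq__(self, other) -> bool:
        return isinstance(other, CommunityTable) and self.df.equals(other.df)

    def __repr__(self) -> str:
        n, m = self.shape
        return f"<CommunityTable: {n} samples x {m} OTUs>"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_community_table(path, format: str = "tsv",
                         orientation: str = "samples_as_rows") -> CommunityTable:
    """Read an OTU count table.

    ``orientation`` declares the layout of a TSV file explicitly
    (``samples_as_rows`` or ``otus_as_rows``); it is never guessed.
    BIOM v1 JSON tables are always observations(=OTUs) x samples and the
    flag is ignored.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if orientation == "otus_as_rows":
            df = df.T
        elif orientation != "samples_as_rows":
            raise ValueError(f"unknown orientation: {orientation!r}")
        return CommunityTable(df)
    if format == "biom-json":
        return _read_biom_json(path)
    raise ValueError(f"unknown format: {format!r}")


def _read_biom_json(path) -> CommunityTable:
    """Minimal BIOM v1 (JSON) reader, dense and sparse dialects."""
    with open(path) as fh:
        doc = json.load(fh)
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    n_obs, n_samp = doc["shape"]
    mat = np.zeros((n_obs, n_samp))
    if doc.get("matrix_type") == "dense":
        mat[:] = np.asarray(doc["data"])
    else:
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    df = pd.DataFrame(mat.T, index=sample_ids, columns=otu_ids)
    return CommunityTable(df)


def write_community_table(table: CommunityTable, path) -> None:
    df = table.df.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_newick(path, default_length: float | None = None) -> TreeNode:
    """Read a rooted Newick tree; tips must be uniquely labelled.

    Branch lengths are required unless ``default_length`` supplies one
    for edges that omit it (the root may always lack a length).
    """
    tree = TreeNode.read(str(path), format="newick")
    tips = [t.name for t in tree.tips()]
    _check_unique(tips, "tip labels")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if default_length is None:
                raise ValidationError(
                    f"node {node.name!r} has no branch length "
                    "(set default_length to allow)")
            node.length = default_length
        elif node.length < 0:
            raise ValidationError(f"negative branch length on {node.name!r}")
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata CSV (sample_id, compartment, region, habitat)."""
    md = pd.read_csv(path, index_col=0, dtype=str)
    _check_unique(md.index, "metadata sample ids")
    for col in ("compartment", "region", "habitat"):
        if col in md.columns and md[col].isna().any():
            raise ValidationError(f"empty {col} values in metadata")
    if "compartment" in md.columns:
        bad = set(md["compartment"]) - set(COMPARTMENTS)
        if bad:
            raise ValidationError(f"unknown compartment labels: {sorted(bad)}")
    return md


def read_soil(path) -> pd.DataFrame:
    """Read and validate a soil/environment property CSV."""
    soil = pd.read_csv(path, index_col=0)
    _check_unique(soil.index, "soil sample ids")
    validate_soil(soil)
    return soil


def validate_soil(soil: pd.DataFrame) -> None:
    num = soil.select_dtypes(include=[np.number])
    if not np.isfinite(num.to_numpy()).all():
        cols = num.columns[~np.isfinite(num).all()].tolist()
        raise ValidationError(f"non-finite soil values in {cols}")
    if "pH" in soil.columns:
        ph = soil["pH"]
        if ((ph <= 0) | (ph >= 14)).any():
            raise ValidationError("pH values outside (0, 14)")
    for col in _NONNEG_SOIL & set(soil.columns):
        if (soil[col] < 0).any():
            raise ValidationError(f"negative values in soil column {col!r}")


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefy(table: CommunityTable, depth: int | str = "min", seed: int = 0,
           drop_empty_otus: bool = True,
           on_small: str = "drop") -> CommunityTable:
    """Subsample every sample to ``depth`` reads without replacement.

    A single seeded multivariate-hypergeometric draw per sample; the seed
    is required for reproducibility. Samples with fewer reads than
    ``depth`` are dropped with a warning (``on_small='drop'``) or raise
    (``on_small='error'``).
    """
    totals = table.sample_totals()
    if depth == "min":
        depth = int(totals.min())
    depth = int(depth)
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    small = totals.index[totals < depth].tolist()
    if small:
        if on_small == "error":
            raise ValidationError(
                f"samples below depth {depth}: {small}")
        logger.warning("rarefy: dropping %d sample(s) below depth %d: %s",
                       len(small), depth, small)
    keep = totals.index[totals >= depth]
    rng = np.random.default_rng(seed)
    out = np.empty((len(keep), table.shape[1]), dtype=np.int64)
    for i, s in enumerate(keep):
        out[i] = rng.multivariate_hypergeometric(
            table.df.loc[s].to_numpy(), depth)
    res = CommunityTable(pd.DataFrame(out, index=keep, columns=table.df.columns))
    if drop_empty_otus:
        res = res.drop_empty_otus()
    return res


# ---------------------------------------------------------------------------
# input alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignedBundle:
    """All inputs subset and reordered to their shared keys."""
    table: CommunityTable
    metadata: pd.DataFrame | None = None
    soil: pd.DataFrame | None = None
    tree: TreeNode | None = None
    taxonomy: pd.DataFrame | None = None
    #: ids dropped from each input, for the run manifest
    dropped: dict = field(default_factory=dict)
    #: OTUs kept in the table but absent from the tree (excluded only
    #: from phylogenetic analyses)
    otus_not_in_tree: list = field(default_factory=list)


def align_inputs(table: CommunityTable, metadata: pd.DataFrame | None = None,
                 soil: pd.DataFrame | None = None,
                 tree: TreeNode | None = None,
                 taxonomy: pd.DataFrame | None = None) -> AlignedBundle:
    """Restrict all inputs to shared sample/OTU keys, reporting drops.

    OTUs missing from the tree remain in the table (they still count for
    compositional analyses) and are listed in ``otus_not_in_tree``; the
    tree itself is sheared to the table's OTUs.
    """
    dropped: dict = {}
    samples = pd.Index(table.sample_ids)
    for name, df in (("metadata", metadata), ("soil", soil)):
        if df is not None:
            samples = samples.intersection(df.index)
    if len(samples) == 0:
        raise ValidationError("no samples shared across inputs")
    if len(samples) < len(table.sample_ids):
        dropped["table_samples"] = sorted(set(table.sample_ids) - set(samples))
    # keep the table's original sample order
    samples = [s for s in table.sample_ids if s in set(samples)]
    table = table.subset(samples=samples)

    if metadata is not None:
        extra = sorted(set(metadata.index) - set(samples))
        if extra:
            dropped["metadata_samples"] = extra
        metadata = metadata.loc[samples]
    if soil is not None:
        extra = sorted(set(soil.index) - set(samples))
        if extra:
            dropped["soil_samples"] = extra
        soil = soil.loc[samples]

    otus_not_in_tree: list = []
    if tree is not None:
        tip_names = {t.name for t in tree.tips()}
        otus_not_in_tree = [o for o in table.otu_ids if o not in tip_names]
        if otus_not_in_tree:
            logger.warning(
                "align_inputs: %d OTU(s) absent from the tree; excluded "
                "from phylogenetic analyses only", len(otus_not_in_tree))
        shared = [o for o in table.otu_ids if o in tip_names]
        if not shared:
            raise ValidationError("no table OTU is a tree tip")
        tree = tree.shear(shared)

    if taxonomy is not None:
        extra = sorted(set(taxonomy.index) - set(table.otu_ids))
        if extra:
            dropped["taxonomy_otus"] = extra
        taxonomy = taxonomy.loc[taxonomy.index.intersection(table.otu_ids)]

    return AlignedBundle(table=table, metadata=metadata, soil=soil,
                         tree=tree, taxonomy=taxonomy, dropped=dropped,
                         otus_not_in_tree=otus_not_in_tree)
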