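"""Rank-level composition summaries, Venn genus partitions, guild joins."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import CommunityTable, ValidationError

logger = logging.getLogger("ecoassembly")

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


def collapse_rank(table: CommunityTable, taxonomy: pd.DataFrame,
                  rank: str) -> CommunityTable:
    """Sum counts over OTUs sharing a taxon label at ``rank``.

    OTUs absent from the taxonomy, or labelled missing/empty, are pooled
    under ``unclassified_<rank>``. Column totals are conserved.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    unk = f"unclassified_{rank}"
    missing = [o for o in table.otu_ids if o not in taxonomy.index]
    if missing:
        logger.warning("collapse_rank: %d OTU(s) missing from taxonomy; "
                       "pooled as %s", len(missing), unk)
    labels = []
    for o in table.otu_ids:
        if o in taxonomy.index and rank in taxonomy.columns:
            lab = taxonomy.loc[o, rank]
            if pd.isna(lab) or str(lab).strip() in ("", "unclassified"):
                lab = unk
        else:
            lab = unk
        labels.append(str(lab))
    collapsed = table.df.T.groupby(pd.Index(labels, name=rank)).sum().T
    return CommunityTable(collapsed)


def relative_abundance(table: CommunityTable, group_by=None) -> pd.DataFrame:
    """Mean per-sample proportions per group (CompositionTable).

    Returns a groups x taxa DataFrame whose rows sum to 1.
    """
    props = table.relative_abundance()
    if group_by is None:
        groups = pd.Series("all", index=props.index)
    else:
        groups = pd.Series(group_by).loc[props.index]
        if groups.isna().any():
            raise ValidationError("group labels do not cover all samples")
    return props.groupby(groups).mean()


def top_k_composition(comp: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Keep the k most abundant taxa overall; pool the rest as 'others'."""
    order = comp.mean(axis=0).sort_values(ascending=False)
    top = list(order.index[:k])
    out = comp[top].copy()
    rest = comp.drop(columns=top)
    if rest.shape[1]:
        out["others"] = rest.sum(axis=1)
    return out


def venn_partition(table: CommunityTable, group_by) -> dict:
    """Shared/unique taxon sets across groups (genus-level Venn).

    Presence in a group = count > 0 in at least one of its samples.
    Percentages are reported over the union of all groups' taxa and,
    separately, over the table's full taxon set.
    """
    groups = pd.Series(group_by).loc[table.df.index]
    labs = sorted(groups.unique())
    if len(labs) < 2:
        raise ValueError("need >= 2 groups")
    present = {}
    for lab in labs:
        sub = table.df[groups == lab]
        present[lab] = set(sub.columns[(sub > 0).any(axis=0)])
    union = set().union(*present.values())
    shared = set.intersection(*present.values())
    unique = {}
    for lab in labs:
        others = union.copy()
        other_sets = [present[o] for o in labs if o != lab]
        unique[lab] = present[lab] - set().union(*other_sets)
    denom_union = max(len(union), 1)
    denom_total = max(table.shape[1], 1)
    return {
        "groups": labs,
        "present": present,
        "shared": shared,
        "unique": unique,
        "shared_pct_of_union": 100.0 * len(shared) / denom_union,
        "shared_pct_of_total": 100.0 * len(shared) / denom_total,
        "unique_pct_of_union": {lab: 100.0 * len(unique[lab]) / denom_union
                                for lab in labs},
    }


def guild_join(table: CommunityTable, taxonomy: pd.DataFrame,
               guild_map: pd.DataFrame, rank: str = "genus",
               label_col: str | None = None) -> pd.DataFrame:
    """Per-sample trophic-mode/guild proportions from a user-supplied map.

    ``guild_map`` has the taxon (at ``rank``) in its index or first
    column and the guild/trophic-mode label in ``label_col`` (default:
    its first non-index column). Taxa without a mapping are pooled under
    ``"unknown"``. Rows sum to 1.
    """
    if guild_map is None or len(guild_map) == 0:
        raise ValidationError("guild_map is empty")
    gm = guild_map.copy()
    if label_col is None:
        label_col = gm.columns[0]
    mapping = gm[label_col].astype(str)
    at_rank = collapse_rank(table, taxonomy, rank)
    labels = [mapping.get(t, "unknown") for t in at_rank.otu_ids]
    merged = at_rank.df.T.groupby(pd.Index(labels, name="guild")).sum().T
    props = merged.div(merged.sum(axis=1), axis=0)
    return props
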