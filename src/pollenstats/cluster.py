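"""Hierarchical clustering of taxa on standardized pollen features.

Taxa are clustered on six variables — P, E, E'/E, RW, FW and PD —
z-scored feature-wise so that micrometre-scale sizes and sub-micron
ornamentation widths contribute comparably to the Euclidean distance.
The dendrogram (Ward linkage by default) is cut at two levels: a top
cut into ``k_top`` groups labelled A, B, C, ... and a second cut of the
largest group's own subtree into ``k_sub`` subgroups (the nested
group/subgroup structure germplasm panels typically show, where one
dominant group holds most cultivars).
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .morphostats import tukey_cld
from .traits import TraitTable, compute_derived_ratios

logger = logging.getLogger(__name__)

#: Default clustering variables: two size axes, the rectangularity
#: ratio, and the three ornamentation indicators.
DEFAULT_FEATURES: tuple[str, ...] = ("P", "E", "Eprime_over_E", "RW", "FW", "PD")

LINKAGES = ("ward", "average", "complete")


@dataclass
class Dendrogram:
    """A scipy linkage matrix plus the leaf labels it refers to."""

    linkage_matrix: np.ndarray
    labels: list[str]
    method: str
    metric: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)


@dataclass
class ClusterResult:
    """Two-level partition of the clustered taxa.

    ``group_of`` maps every taxon to a top-level letter; ``subgroup_of``
    maps only members of the largest group to numbered sublabels (e.g.
    D1, D2, D3).
    """

    dendrogram: Dendrogram
    group_of: dict[str, str]
    subgroup_of: dict[str, str]
    largest_group: str
    feature_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def effective_label(self, taxon: str, level: str = "four_group") -> str:
        """Group letter, or — at ``six_group`` level — the subgroup
        label for members of the largest group."""
        if level == "four_group":
            return self.group_of[taxon]
        if level == "six_group":
            return self.subgroup_of.get(taxon, self.group_of[taxon])
        raise ValueError(f"unknown level {level!r}")

    @property
    def taxa(self) -> list[str]:
        return list(self.group_of)


def build_feature_matrix(
    table: TraitTable,
    derived: pd.DataFrame | None = None,
    features: Sequence[str] = DEFAULT_FEATURES,
) -> pd.DataFrame:
    """Per-taxon feature matrix, z-scored feature-wise (ddof 0).

    Raw traits come from per-taxon replicate means; ratio features from
    ``derived`` (computed on the fly if omitted). Taxa missing any
    requested feature are excluded with a logged list. Standardization
    parameters are kept in ``result.attrs["standardization"]``.
    """
    means = table.taxon_means()
    if derived is None:
        derived = compute_derived_ratios(table)
    pool = means.join(derived, how="left")
    missing = [f for f in features if f not in pool.columns]
    if missing:
        raise ValueError(f"unavailable feature(s) {missing}")
    X = pool.loc[:, list(features)]
    dropped = X.index[X.isna().any(axis=1)].tolist()
    if dropped:
        logger.warning("excluding %d taxa lacking features: %s",
                       len(dropped), dropped)
        X = X.dropna()
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    # constant up to representation noise counts as zero-variance
    flat = sd.index[sd <= 1e-12 * np.maximum(np.abs(mu), 1.0)]
    if len(flat):
        raise ValueError(
            f"feature {flat[0]!r} is constant across taxa; cannot standardize")
    Z = (X - mu) / sd
    Z.attrs["standardization"] = pd.DataFrame({"mean": mu, "sd": sd})
    Z.attrs["excluded_taxa"] = dropped
    return Z


def hierarchical_cluster(
    features: pd.DataFrame,
    linkage: str = "ward",
    distance: str = "euclidean",
) -> Dendrogram:
    """Agglomerative merge tree over the feature rows."""
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if len(features) < 2:
        raise ValueError("need at least 2 taxa to cluster")
    X = features.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("NaN or infinite value in feature matrix")
    Z = hierarchy.linkage(X, method=linkage, metric=distance)
    return Dendrogram(linkage_matrix=Z, labels=list(features.index),
                      method=linkage, metric=distance)


def _cut_nodes(roots: list, k: int) -> list:
    """Cut a (sub)tree into k clusters by repeatedly splitting the
    highest remaining merge; valid because merge heights are
    non-decreasing for the supported linkages."""
    nodes = list(roots)
    while len(nodes) < k:
        internal = [n for n in nodes if not n.is_leaf()]
        if not internal:
            raise ValueError(f"cannot cut into {k} clusters: too few leaves")
        top = max(internal, key=lambda n: (n.dist, n.get_count()))
        nodes.remove(top)
        nodes.extend([top.get_left(), top.get_right()])
    return nodes


def _leaves(node) -> list[int]:
    return node.pre_order(lambda x: x.id)


def cut_two_level(
    dendrogram: Dendrogram, k_top: int = 4, k_sub: int = 3
) -> ClusterResult:
    """Top cut into ``k_top`` groups, then re-cut the largest group's
    subtree into ``k_sub`` subgroups.

    Letters are assigned by ascending group size (ties broken by
    dendrogram leaf order), so the largest group always carries the
    last letter; subgroups are numbered the same way within it. Labels
    are presentation — the partition itself is what downstream
    statistics consume.
    """
    n = dendrogram.n_leaves
    if k_top > n:
        raise ValueError(f"k_top={k_top} exceeds {n} taxa")
    root = hierarchy.to_tree(dendrogram.linkage_matrix)
    top_nodes = _cut_nodes([root], k_top)
    leaf_pos = {leaf: i for i, leaf in
                enumerate(hierarchy.leaves_list(dendrogram.linkage_matrix))}
    labels = dendrogram.labels

    def sort_key(node):
        ids = _leaves(node)
        return (len(ids), min(leaf_pos[i] for i in ids))

    ordered = sorted(top_nodes, key=sort_key)
    letters = string.ascii_uppercase[:k_top]
    group_of: dict[str, str] = {}
    for letter, node in zip(letters, ordered):
        for i in _leaves(node):
            group_of[labels[i]] = letter
    largest_node = ordered[-1]
    largest_letter = letters[-1]

    subgroup_of: dict[str, str] = {}
    if k_sub > 1 and largest_node.get_count() >= k_sub:
        sub_nodes = sorted(_cut_nodes([largest_node], k_sub), key=sort_key)
        for j, node in enumerate(sub_nodes, start=1):
            for i in _leaves(node):
                subgroup_of[labels[i]] = f"{largest_letter}{j}"
    elif k_sub > 1:
        logger.warning("largest group has %d members; skipping %d-way sub-cut",
                       largest_node.get_count(), k_sub)
    group_of = {labels[i]: group_of[labels[i]] for i in sorted(leaf_pos,
                key=leaf_pos.get)}
    return ClusterResult(dendrogram=dendrogram, group_of=group_of,
                         subgroup_of=subgroup_of,
                         largest_group=largest_letter)


#: Traits summarized per cluster group (size, shape ratios, ornamentation).
SUMMARY_TRAITS = ("P", "E", "Eprime", "S", "P_over_E", "P_over_Eprime",
                  "Eprime_over_E", "RW", "FW", "PD")


def group_summaries(
    table: TraitTable,
    result: ClusterResult,
    derived: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-group trait mean +/- sd with Tukey letters, over taxa.

    Tukey HSD compares groups on per-taxon means (the units of the
    summary are taxa); letters are computed separately at the group and
    subgroup level. Groups of one taxon report a missing sd.
    """
    if derived is None:
        derived = compute_derived_ratios(table)
    pool = table.taxon_means().join(derived, how="left")
    rows = []
    for level, mapping in (("group", result.group_of),
                           ("subgroup", result.subgroup_of)):
        if not mapping:
            continue
        by_label: dict[str, list[str]] = {}
        for taxon, label in mapping.items():
            by_label.setdefault(label, []).append(taxon)
        for trait in SUMMARY_TRAITS:
            if trait not in pool.columns:
                continue
            groups = {
                lab: pool.loc[taxa, trait].dropna().to_numpy()
                for lab, taxa in by_label.items()
            }
            groups = {k: v for k, v in groups.items() if len(v) > 0}
            letters = {}
            if len(groups) >= 2 and all(len(v) >= 1 for v in groups.values()):
                try:
                    letters = tukey_cld(groups, alpha=alpha).letters
                except Exception as exc:  # degenerate designs
                    logger.warning("CLD failed for %s/%s: %s", level, trait, exc)
            for lab in sorted(groups):
                v = groups[lab]
                rows.append({
                    "level": level, "label": lab, "trait": trait,
                    "n": len(v), "mean": float(v.mean()),
                    "sd": float(v.std(ddof=1)) if len(v) > 1 else float("nan"),
                    "letter": letters.get(lab, ""),
                })
    return pd.DataFrame(rows)


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick export; branch length = parent merge height minus child
    merge height (leaves hang from their first merge)."""
    root = hierarchy.to_tree(dendrogram.linkage_matrix)
    labels = dendrogram.labels

    def fmt(node, parent_dist: float) -> str:
        length = parent_dist - node.dist
        if node.is_leaf():
            name = labels[node.id].replace(" ", "_").replace(",", "_")
            return f"{name}:{length:.6g}"
        left = fmt(node.get_left(), node.dist)
        right = fmt(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return fmt(root, root.dist) + ";"
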