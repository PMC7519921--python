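"""Hierarchical clustering of candidate variants over allele-frequency profiles.

Each selected variant is represented by its allele-frequency profile across
populations (the two cohort populations, optionally extended with
user-supplied reference-panel frequency columns).  Variants are clustered
agglomeratively over these profiles, the tree is cut, and one representative
per cluster — the variant with the largest between-population frequency
contrast — is kept, restricted to variants carrying a gene annotation (gene
assignment is consumed from an external table, never computed here).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import ConfigurationError, ValidationError
from .popgen import FrequencyTable

logger = logging.getLogger(__name__)


@dataclass
class FrequencyProfileMatrix:
    """Variants x populations allele-frequency matrix (no undefined entries)."""

    profiles: pd.DataFrame  # index: variant id; columns: population labels

    def __post_init__(self) -> None:
        if self.profiles.shape[1] < 2:
            raise ValidationError("need >= 2 population columns")
        vals = self.profiles.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValidationError("profile matrix contains undefined entries")
        if ((vals < 0) | (vals > 1)).any():
            raise ValidationError("frequencies must lie in [0, 1]")

    @property
    def variant_ids(self) -> list:
        return list(self.profiles.index)

    def contrast(self) -> pd.Series:
        """Per-variant max - min frequency across population columns."""
        return self.profiles.max(axis=1) - self.profiles.min(axis=1)


def build_profiles(
    freqs: FrequencyTable | pd.DataFrame,
    variant_subset: list,
    extra_columns: pd.DataFrame | None = None,
) -> FrequencyProfileMatrix:
    """Assemble the frequency-profile matrix for a variant subset.

    ``freqs`` is a cohort :class:`~pygmyscan.popgen.FrequencyTable` (its
    variant ids index the rows) or a ready DataFrame indexed by variant id.
    ``extra_columns`` may add reference-panel frequencies, joined on variant
    id.  Variants undefined in any population are dropped and logged.
    """
    if not len(variant_subset):
        raise ValidationError("empty variant subset")
    if isinstance(freqs, FrequencyTable):
        if freqs.variants is None:
            raise ValidationError("frequency table carries no variant index")
        table = freqs.freq.copy()
        table.index = pd.Index(freqs.variants["id"], name="variant_id")
    else:
        table = freqs.copy()

    missing_ids = [v for v in variant_subset if v not in table.index]
    if missing_ids:
        raise ValidationError(
            f"{len(missing_ids)} subset variants absent from frequency table"
        )
    sub = table.loc[list(variant_subset)]
    if extra_columns is not None:
        sub = sub.join(extra_columns, how="left")

    defined = sub.notna().all(axis=1)
    n_dropped = int((~defined).sum())
    if n_dropped:
        logger.info("build_profiles: dropped %d variants undefined in >= 1 "
                    "population", n_dropped)
    sub = sub.loc[defined]
    if sub.empty:
        raise ValidationError("no variant defined in every population")
    return FrequencyProfileMatrix(sub)


@dataclass
class Dendrogram:
    """Merge tree over variants with the linkage/metric that produced it."""

    linkage_matrix: np.ndarray  # scipy (n-1) x 4 linkage encoding
    leaf_ids: list
    linkage: str
    metric: str

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def cut(self, n_clusters: int | None = None, height: float | None = None
            ) -> np.ndarray:
        """Flat cluster labels (1..k) by cluster count or merge height."""
        if (n_clusters is None) == (height is None):
            raise ConfigurationError("give exactly one of n_clusters, height")
        if n_clusters is not None:
            if not (1 <= n_clusters <= self.n_leaves):
                raise ConfigurationError(
                    f"n_clusters must lie in [1, {self.n_leaves}]"
                )
            return hierarchy.fcluster(
                self.linkage_matrix, t=n_clusters, criterion="maxclust"
            )
        if height < 0:
            raise ConfigurationError("height must be >= 0")
        return hierarchy.fcluster(self.linkage_matrix, t=height,
                                  criterion="distance")

    def to_newick(self) -> str:
        """Serialize the merge tree as a Newick string with branch lengths."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.leaf_ids[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        inner = (
            f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"
            if not tree.is_leaf()
            else f"{self.leaf_ids[tree.id]};"
        )
        return inner


def cluster_variants(
    profiles: FrequencyProfileMatrix,
    linkage: str = "complete",
    metric: str = "euclidean",
) -> Dendrogram:
    """Agglomerative clustering of variant rows; deterministic given inputs."""
    if linkage not in ("complete", "average", "ward"):
        raise ConfigurationError(f"unsupported linkage: {linkage!r}")
    if metric not in ("euclidean", "correlation"):
        raise ConfigurationError(f"unsupported metric: {metric!r}")
    X = profiles.profiles.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("need >= 2 variants to cluster")
    if metric == "correlation":
        if np.any(X.std(axis=1) == 0):
            raise ValidationError(
                "correlation metric undefined on constant frequency profiles"
            )
    if linkage == "ward" and metric != "euclidean":
        raise ConfigurationError("ward linkage requires the euclidean metric")
    Z = hierarchy.linkage(pdist(X, metric=metric), method=linkage)
    return Dendrogram(Z, profiles.variant_ids, linkage, metric)


def shortlist(
    dendrogram: Dendrogram,
    profiles: FrequencyProfileMatrix,
    annotation: pd.DataFrame,
    n_clusters: int | None = None,
    height: float | None = None,
) -> pd.DataFrame:
    """Cut the tree and keep one gene-annotated representative per cluster.

    ``annotation`` maps variant id to at least a ``gene`` column (and
    optionally a ``localization`` class).  Within each cluster the variant
    with the largest between-population frequency contrast represents the
    cluster (ties broken by position in the profile matrix); representatives
    without a gene annotation are then discarded.  Result is ordered by
    contrast descending.
    """
    if "gene" not in annotation.columns:
        raise ValidationError("annotation needs a 'gene' column")
    labels = dendrogram.cut(n_clusters=n_clusters, height=height)
    contrast = profiles.contrast()
    ids = profiles.variant_ids

    reps: list[tuple] = []
    for cl in np.unique(labels):
        members = [i for i in range(len(ids)) if labels[i] == cl]
        best = max(members, key=lambda i: (contrast.iloc[i], -i))
        reps.append((ids[best], cl, float(contrast.iloc[best])))

    rows = []
    for vid, cl, ctr in reps:
        if vid in annotation.index and pd.notna(annotation.loc[vid, "gene"]):
            ann = annotation.loc[vid]
            rows.append(
                {
                    "variant_id": vid,
                    "cluster": int(cl),
                    "gene": ann["gene"],
                    "localization": ann.get("localization", ""),
                    "contrast": ctr,
                }
            )
    if not rows:
        warnings.warn("shortlist: no cluster representative carries a gene "
                      "annotation", stacklevel=2)
        return pd.DataFrame(
            columns=["variant_id", "cluster", "gene", "localization", "contrast"]
        )
    out = pd.DataFrame(rows)
    return out.sort_values("contrast", ascending=False,
                           kind="stable").reset_index(drop=True)
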