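"""Relative tissue expression profiles and tissue-level hierarchical clustering.

For an overview of how the five tissues relate — before any fold-change
criteria — each protein's per-tissue level (mean over experiments of the
normalized, imputed intensity) is divided by its across-tissue mean:

    L[p, t] = mean_e I_hat[p, e, t] / mean_t mean_e I_hat[p, e, t]

so every protein's profile averages to 1 across tissues.  The tissues are
then clustered agglomeratively with distance 1 - Pearson correlation of
their profile columns and unweighted average linkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .errors import ValidationError
from .tables_io import IntensityTable
from .tissues import Tissue


def relative_profiles(
    table: IntensityTable,
    restrict_min_experiments: int | None = 2,
    log_profiles: bool = False,
) -> pd.DataFrame:
    """Per-protein relative tissue levels (rows average to 1 across tissues).

    The table must be normalized and imputed.  When
    ``restrict_min_experiments`` is set (default 2), only proteins identified
    in at least that many experiments enter — the clustering population, with
    no fold-change criteria applied.  ``log_profiles`` returns ln(L) instead
    of L (the row-mean-1 invariant then applies to exp of the values).
    """
    if restrict_min_experiments is not None:
        presence = table.presence_by_experiment()
        keep = presence.sum(axis=1) >= restrict_min_experiments
        table = table.replace(
            values=table.values.loc[keep],
            meta=table.meta.loc[keep],
            detected=table.detected.loc[keep],
        )
    tissue_level = table.values.T.groupby(level=1, sort=False).mean().T
    tissue_level = tissue_level[[t.value for t in table.tissues]]
    denom = tissue_level.mean(axis=1)
    if (denom <= 0).any():
        raise ValidationError("protein with nonpositive mean level; impute zeros first")
    L = tissue_level.div(denom, axis=0)
    return np.log(L) if log_profiles else L


@dataclass
class TissueDendrogram:
    """Binary merge tree over tissues from average-linkage clustering.

    ``linkage_matrix`` is in scipy ``linkage`` format; ``tissues`` gives the
    leaf order corresponding to observation indices.
    """

    tissues: list[Tissue]
    linkage_matrix: np.ndarray
    distance: pd.DataFrame  # the pairwise 1 - r matrix

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def newick(self) -> str:
        """Serialize as a Newick string with branch lengths from merge heights."""
        tree = to_tree(self.linkage_matrix)

        def name(leaf_id: int) -> str:
            label = self.tissues[leaf_id].display_name
            return f"'{label}'" if any(c in label for c in " ,():;") else label

        def height(node) -> float:
            return 0.0 if node.is_leaf() else float(node.dist)

        def render(node, parent_height: float) -> str:
            length = parent_height - height(node)
            if node.is_leaf():
                return f"{name(node.id)}:{length:.10g}"
            left = render(node.left, height(node))
            right = render(node.right, height(node))
            return f"({left},{right}):{length:.10g}"

        root_h = height(tree)
        left = render(tree.left, root_h)
        right = render(tree.right, root_h)
        return f"({left},{right});"


def cluster_tissues(profiles: pd.DataFrame) -> TissueDendrogram:
    """Average-linkage clustering of tissues on 1 - Pearson correlation.

    ``profiles`` is a protein x tissue frame of relative levels.  Proteins
    with any undefined value are dropped (complete-case across tissues).
    Equal minimum distances are resolved deterministically by the tissue
    enum order of the input columns.
    """
    P = profiles.dropna(axis=0, how="any")
    if len(P) < 2:
        raise ValidationError("clustering needs >= 2 proteins with defined profiles")
    X = P.to_numpy(dtype=float).T  # tissue x protein
    sd = X.std(axis=1)
    for i, code in enumerate(P.columns):
        if sd[i] == 0:
            raise ValidationError(
                f"tissue {code} has a zero-variance profile; correlation undefined"
            )
    corr = np.corrcoef(X)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrize fp noise
    Z = linkage(squareform(dist, checks=False), method="average")
    tissues = [Tissue.from_code(c) for c in P.columns]
    ddist = pd.DataFrame(dist, index=P.columns, columns=P.columns)
    return TissueDendrogram(tissues, Z, ddist)


def export_newick(tree: TissueDendrogram, path: str | Path) -> None:
    """Write the dendrogram as a Newick file."""
    Path(path).write_text(tree.newick() + "\n", encoding="utf-8")


class TissueProfileClusterer(BaseEstimator):
    """Relative-profile computation plus tissue clustering as one estimator.

    Parameters
    ----------
    restrict_min_experiments : int or None
        Minimum experiments a protein must be identified in to enter the
        profile population (None = no restriction).
    log_profiles : bool
        Cluster on ln-transformed relative levels instead of linear ones.

    Attributes
    ----------
    profiles_ : pandas.DataFrame
    dendrogram_ : TissueDendrogram
    """

    def __init__(self, restrict_min_experiments: int | None = 2, log_profiles: bool = False):
        self.restrict_min_experiments = restrict_min_experiments
        self.log_profiles = log_profiles

    def fit(self, X: IntensityTable, y=None) -> "TissueProfileClusterer":
        self.profiles_ = relative_profiles(
            X, self.restrict_min_experiments, self.log_profiles
        )
        self.dendrogram_ = cluster_tissues(self.profiles_)
        return self
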