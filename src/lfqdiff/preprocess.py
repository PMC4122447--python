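"""Preprocessing: normalization, presence filtering, zero imputation, overlap stats.

The pipeline order is fixed as normalize -> filter -> impute:

1. every (experiment, tissue) sample is rescaled so its summed intensity
   equals the grand mean of the original per-sample sums (total-intensity
   normalization, as used when equal protein amounts are loaded per sample);
2. proteins identified in fewer than ``min_experiments`` experiments are
   removed (a protein is "identified in an experiment" when it has nonzero
   intensity in at least one of that experiment's tissues);
3. remaining zeros (non-detections) are replaced by ``factor`` x the lowest
   positive intensity of the whole dataset, so that ratios against
   below-detection-limit values are defined.

The imputation floor is computed over the normalized, filtered dataset as a
whole; a per-experiment variant is available via ``scope="experiment"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ValidationError
from .tables_io import IntensityTable
from .tissues import Tissue


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class EqualSumNormalizer(TransformerMixin, BaseEstimator):
    """Scale each (experiment, tissue) sample to a common summed intensity.

    The common target is the grand mean of the original per-sample sums, so
    the overall intensity scale of the dataset is preserved and all samples
    are treated symmetrically.

    Attributes
    ----------
    scale_factors_ : pandas.Series
        Multiplicative factor per (experiment, tissue) sample.
    target_sum_ : float
        The common post-normalization sample sum.
    """

    def fit(self, X: IntensityTable, y=None) -> "EqualSumNormalizer":
        sums = X.values.sum(axis=0)
        zero = sums[sums <= 0]
        if len(zero):
            exp, code = zero.index[0]
            raise ValidationError(
                f"sample (experiment={exp!r}, tissue={code!r}) has no positive intensity"
            )
        self.target_sum_ = float(sums.mean())
        self.scale_factors_ = self.target_sum_ / sums
        return self

    def transform(self, X: IntensityTable) -> IntensityTable:
        factors = self.scale_factors_
        if not factors.index.equals(X.values.columns):
            raise ValidationError("table samples do not match the fitted scale factors")
        return X.replace(values=X.values * factors, detected=X.detected)


class ExperimentPresenceFilter(TransformerMixin, BaseEstimator):
    """Drop proteins identified in fewer than ``min_experiments`` experiments.

    With the default of 2 this removes single-experiment identifications,
    which carry no replicate information for the differential statistics.
    """

    def __init__(self, min_experiments: int = 2):
        self.min_experiments = min_experiments

    def fit(self, X: IntensityTable, y=None) -> "ExperimentPresenceFilter":
        k = int(self.min_experiments)
        if not 1 <= k <= X.n_experiments:
            raise ValidationError(
                f"min_experiments={k} outside [1, {X.n_experiments}]"
            )
        presence = X.presence_by_experiment()
        self.kept_accessions_ = presence.index[presence.sum(axis=1) >= k]
        return self

    def transform(self, X: IntensityTable) -> IntensityTable:
        keep = X.values.index.isin(self.kept_accessions_)
        return X.replace(
            values=X.values.loc[keep],
            meta=X.meta.loc[keep],
            detected=X.detected.loc[keep],
        )


class DetectionFloorImputer(TransformerMixin, BaseEstimator):
    """Replace zero intensities with ``factor`` x the lowest positive intensity.

    Zeros encode below-detection-limit measurements; replacing them with a
    small positive floor makes ratios against them finite while keeping them
    clearly separated from genuinely quantified values.  The pre-imputation
    detection pattern is preserved in the table's ``detected`` mask.

    Parameters
    ----------
    factor : float
        Multiple of the minimum positive intensity used as the floor.
    scope : {"global", "experiment"}
        Whether the minimum is taken over the whole dataset (default) or
        separately within each experiment.
    """

    def __init__(self, factor: float = 3.0, scope: str = "global"):
        self.factor = factor
        self.scope = scope

    def fit(self, X: IntensityTable, y=None) -> "DetectionFloorImputer":
        if not self.factor > 0:
            raise ValidationError("imputation factor must be positive")
        if self.scope not in ("global", "experiment"):
            raise ValidationError(f"unknown imputation scope {self.scope!r}")
        vals = X.values.to_numpy(dtype=float)
        pos = vals[vals > 0]
        if pos.size == 0:
            raise ValidationError("cannot impute: table has no positive intensity")
        if self.scope == "global":
            self.imputation_value_ = float(self.factor * pos.min())
        else:
            per_exp = {}
            for exp in X.experiments:
                sub = X.values[exp].to_numpy(dtype=float)
                p = sub[sub > 0]
                if p.size == 0:
                    raise ValidationError(
                        f"cannot impute: experiment {exp!r} has no positive intensity"
                    )
                per_exp[exp] = float(self.factor * p.min())
            self.imputation_value_ = per_exp
        return self

    def transform(self, X: IntensityTable) -> IntensityTable:
        values = X.values.copy()
        if self.scope == "global":
            values[values == 0] = self.imputation_value_
        else:
            for exp, code in values.columns:
                col = values[(exp, code)]
                values[(exp, code)] = col.mask(col == 0, self.imputation_value_[exp])
        return X.replace(values=values, detected=X.detected)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def normalize_equal_sum(table: IntensityTable) -> IntensityTable:
    """Equal-sum normalization; see :class:`EqualSumNormalizer`."""
    return EqualSumNormalizer().fit_transform(table)


def filter_by_experiment_presence(
    table: IntensityTable, min_experiments: int = 2
) -> IntensityTable:
    """Keep proteins identified in at least ``min_experiments`` experiments."""
    return ExperimentPresenceFilter(min_experiments).fit_transform(table)


def impute_zeros(
    table: IntensityTable, factor: float = 3.0, scope: str = "global"
) -> IntensityTable:
    """Replace zeros with ``factor`` x the minimum positive intensity."""
    return DetectionFloorImputer(factor=factor, scope=scope).fit_transform(table)


# ---------------------------------------------------------------------------
# identification statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapSummary:
    """Identification overlap between experiments."""

    n_total: int
    n_at_least_two: int
    n_all: int
    per_experiment: dict[str, int]

    def __post_init__(self):
        if not (0 <= self.n_all <= self.n_at_least_two <= self.n_total):
            raise ValidationError("overlap counts violate n_all <= n_>=2 <= n_total")


def overlap_summary(table: IntensityTable) -> OverlapSummary:
    """Count unique proteins and their sharing across experiments.

    A protein counts as identified in an experiment when it is detected
    (nonzero pre-imputation) in at least one tissue of that experiment.
    """
    presence = table.presence_by_experiment()
    n_by_protein = presence.sum(axis=1)
    n_exp = table.n_experiments
    # sharing statistics are about agreement between experiments; degenerate
    # single-experiment tables have no sharing by definition
    at_least_two = int((n_by_protein >= 2).sum()) if n_exp >= 2 else 0
    n_all = int((n_by_protein == n_exp).sum()) if n_exp >= 2 else 0
    return OverlapSummary(
        n_total=int((n_by_protein >= 1).sum()),
        n_at_least_two=at_least_two,
        n_all=n_all,
        per_experiment={e: int(presence[e].sum()) for e in presence.columns},
    )


def replicate_consistency(table: IntensityTable) -> tuple[dict[Tissue, float], float]:
    """Per-tissue replicate detection consistency, on the all-experiment proteins.

    Restricting to proteins identified in every experiment (in any tissue),
    compute for each tissue the percentage of proteins, among those detected
    in that tissue at least once, that are detected in that tissue in *every*
    experiment.  Returns the per-tissue percentages (``nan`` where the
    denominator is empty) and their unweighted mean over defined tissues.
    """
    presence = table.presence_by_experiment()
    core = presence.index[presence.sum(axis=1) == table.n_experiments]
    det = table.detected.loc[core]
    percentages: dict[Tissue, float] = {}
    vals = []
    for tissue in table.tissues:
        sub = det.xs(tissue.value, axis=1, level=1)
        ever = sub.any(axis=1)
        denom = int(ever.sum())
        if denom == 0:
            percentages[tissue] = float("nan")
            continue
        always = int((sub.sum(axis=1) == sub.shape[1])[ever].sum())
        pct = 100.0 * always / denom
        percentages[tissue] = pct
        vals.append(pct)
    mean = float(np.mean(vals)) if vals else float("nan")
    return percentages, mean
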