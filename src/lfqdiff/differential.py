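"""Pairwise tissue differential analysis on natural-log intensity ratios.

For one ordered tissue pair (numerator, denominator), each protein has up to
E replicate ln-ratios, one per experiment:

    r[p, e] = ln( I_hat[p, e, num] / I_hat[p, e, den] )

computed on normalized, zero-imputed intensities.  A replicate contributes no
ratio when the protein was undetected (pre-imputation) in *both* tissues of
that experiment, and a protein enters the comparison only with >= 2 defined
replicates.

The differential-level threshold is 2 x a *global* standard error of the
mean: replicate variation is pooled over all quantified proteins of the
comparison rather than estimated per protein,

    sd_global  = sqrt( sum_p sum_e (r[p,e] - rbar[p])^2 / sum_p (n_p - 1) )
    sem_global = sd_global / sqrt(E)
    threshold  = 2 * sem_global        (ln units)

Two tiers of differential proteins are called:

* Group A — quantified in all E experiments, two-tailed one-sample t-test of
  the ln-ratios against 0 with p < alpha, and |mean ln-ratio| > threshold;
* Group B — tested only on A-failures: every defined |r[p,e]| > threshold
  with a common sign (>= 2 replicates).  Group B proteins with all E
  replicates are flagged ``B_triplicate`` ("b(t)" in report tables).

No multiple-testing correction is applied beyond the combined t + fold-change
rule; this mirrors the two-tier filtering design the pipeline implements and
is documented prominently in the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import UsageError, ValidationError
from .tables_io import IntensityTable
from .tissues import Tissue

GROUPS = ("A", "B", "B_triplicate", "none")
PASSING = frozenset({"A", "B", "B_triplicate"})

#: Precedence used when ranking: stronger evidence first.
GROUP_PRECEDENCE = {"A": 3, "B_triplicate": 2, "B": 1, "none": 0}


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------

@dataclass
class LnRatioSet:
    """Per-protein, per-experiment ln-ratios for one ordered tissue pair."""

    numerator: Tissue
    denominator: Tissue
    ratios: pd.DataFrame  # index accession, columns experiments; NaN = no ratio

    @property
    def n_experiments(self) -> int:
        return self.ratios.shape[1]

    @property
    def comparison(self) -> str:
        return f"{self.numerator.value}_vs_{self.denominator.value}"


@dataclass(frozen=True)
class GlobalSpread:
    """Pooled replicate spread of ln-ratios for one comparison."""

    numerator: Tissue
    denominator: Tissue
    sd_global: float
    sem_global: float
    threshold: float  # = 2 * sem_global, ln units
    n_proteins: int   # proteins contributing to the pooled estimate

    def __post_init__(self):
        if self.sd_global < 0:
            raise ValidationError("sd_global must be nonnegative")
        if not math.isclose(self.threshold, 2.0 * self.sem_global, rel_tol=1e-12):
            raise ValidationError("threshold must equal 2 x sem_global")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def compute_ln_ratios(
    table: IntensityTable, num: Tissue, den: Tissue
) -> LnRatioSet:
    """Within-experiment ln-ratios ``ln(I_num / I_den)`` for an ordered pair.

    The table must already be zero-imputed.  Replicates where the protein was
    undetected in both tissues contribute ``NaN``.
    """
    if num == den:
        raise UsageError(f"numerator and denominator are both {num.value}")
    num_vals = table.values.xs(num.value, axis=1, level=1)
    den_vals = table.values.xs(den.value, axis=1, level=1)
    if (num_vals.to_numpy() <= 0).any() or (den_vals.to_numpy() <= 0).any():
        raise ValidationError("table contains zeros; impute before computing ratios")
    r = np.log(num_vals.to_numpy() / den_vals.to_numpy())
    either_detected = (
        table.detected.xs(num.value, axis=1, level=1).to_numpy()
        | table.detected.xs(den.value, axis=1, level=1).to_numpy()
    )
    r = np.where(either_detected, r, np.nan)
    ratios = pd.DataFrame(r, index=table.values.index, columns=num_vals.columns)
    return LnRatioSet(num, den, ratios)


def global_spread(ratios: LnRatioSet, method: str = "pooled") -> GlobalSpread:
    """Estimate the global ln-ratio spread and the 2 x SEM threshold.

    ``method`` selects the spread estimator:

    * ``"pooled"`` (default): pooled within-protein standard deviation over
      proteins with >= 2 defined ratios — the replicate-noise reading of a
      "global standard error of the mean";
    * ``"all_ratios"``: plain standard deviation of all defined ln-ratios;
    * ``"mean_ratios"``: standard deviation of the per-protein mean ln-ratios.
    """
    R = ratios.ratios.to_numpy(dtype=float)
    n_def = np.sum(~np.isnan(R), axis=1)
    usable = n_def >= 2
    if usable.sum() < 2:
        raise ValidationError(
            "global spread needs >= 2 proteins with >= 2 defined ratios"
        )
    if method == "pooled":
        sub = R[usable]
        means = np.nanmean(sub, axis=1, keepdims=True)
        ss = np.nansum((sub - means) ** 2)
        dof = int(np.sum(n_def[usable] - 1))
        sd = math.sqrt(ss / dof)
    elif method == "all_ratios":
        sd = float(np.nanstd(R[usable], ddof=1))
    elif method == "mean_ratios":
        sd = float(np.std(np.nanmean(R[usable], axis=1), ddof=1))
    else:
        raise UsageError(f"unknown spread method {method!r}")
    sem = sd / math.sqrt(ratios.n_experiments)
    return GlobalSpread(
        ratios.numerator, ratios.denominator,
        sd_global=sd, sem_global=sem, threshold=2.0 * sem,
        n_proteins=int(usable.sum()),
    )


def _one_sample_t_pvalues(R: np.ndarray) -> np.ndarray:
    """Two-tailed one-sample t p-values of each row's defined ratios against 0.

    Rows with < 2 defined ratios get NaN.  Degenerate zero-variance rows get
    p = 0 when the mean is nonzero (the t statistic diverges) and p = 1 when
    all ratios are exactly 0.
    """
    n = np.sum(~np.isnan(R), axis=1)
    mean = np.full(R.shape[0], np.nan)
    sd = np.full(R.shape[0], np.nan)
    ok = n >= 2
    mean[ok] = np.nanmean(R[ok], axis=1)
    sd[ok] = np.nanstd(R[ok], axis=1, ddof=1)
    p = np.full(R.shape[0], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    regular = ok & (sd > 0)
    p[regular] = 2.0 * stats.t.sf(np.abs(t[regular]), df=n[regular] - 1)
    degenerate = ok & (sd == 0)
    p[degenerate] = np.where(mean[degenerate] != 0, 0.0, 1.0)
    return p


def classify_groups(
    ratios: LnRatioSet,
    spread: GlobalSpread,
    alpha: float = 0.05,
    require_common_sign: bool = True,
) -> pd.DataFrame:
    """Assign each protein to Group A, B, B_triplicate or none.

    Returns a DataFrame indexed by accession with columns ``n_replicates``,
    ``mean_lnFC``, ``fold_change``, ``p_value``, ``direction`` and ``group``.
    Proteins with < 2 defined ratios are reported with group ``none`` and an
    undefined p-value.
    """
    if (spread.numerator, spread.denominator) != (ratios.numerator, ratios.denominator):
        raise UsageError("spread was computed for a different comparison")
    R = ratios.ratios.to_numpy(dtype=float)
    E = ratios.n_experiments
    thr = spread.threshold
    n = np.sum(~np.isnan(R), axis=1)
    # nanmean over all-NaN rows warns; compute row means only where defined
    mean = np.full(R.shape[0], np.nan)
    rows = n > 0
    if rows.any():
        mean[rows] = np.nanmean(R[rows], axis=1)
    p = _one_sample_t_pvalues(R)

    eligible = n >= 2
    group_a = eligible & (n == E) & (p < alpha) & (np.abs(mean) > thr)

    abs_ok = np.zeros(R.shape[0], dtype=bool)
    sign_ok = np.zeros(R.shape[0], dtype=bool)
    if eligible.any():
        with np.errstate(invalid="ignore"):
            exceeds = np.abs(R) > thr
        defined = ~np.isnan(R)
        abs_ok = np.where(defined, exceeds, True).all(axis=1)
        pos_all = np.where(defined, R > 0, True).all(axis=1)
        neg_all = np.where(defined, R < 0, True).all(axis=1)
        sign_ok = pos_all | neg_all if require_common_sign else np.ones(R.shape[0], bool)
    group_b = eligible & ~group_a & abs_ok & sign_ok

    group = np.full(R.shape[0], "none", dtype=object)
    group[group_b & (n == E)] = "B_triplicate"
    group[group_b & (n < E)] = "B"
    group[group_a] = "A"

    direction = np.where(mean > 0, "up", "down")
    # undefined for unquantified proteins and exactly balanced ratios
    direction = np.where(np.isnan(mean) | (mean == 0), "", direction)
    return pd.DataFrame(
        {
            "n_replicates": n.astype(int),
            "mean_lnFC": mean,
            "fold_change": np.exp(mean),
            "p_value": p,
            "direction": direction,
            "group": group,
        },
        index=ratios.ratios.index,
    )


def passing_counts(results: pd.DataFrame) -> dict[str, int]:
    """Counts of Group A, Group B (incl. triplicate) and total passing proteins."""
    g = results["group"]
    n_a = int((g == "A").sum())
    n_b = int(g.isin(["B", "B_triplicate"]).sum())
    return {"A": n_a, "B": n_b, "total": n_a + n_b}


def magnitude_fold_change(fc: float) -> float:
    """Fold change on the >= 1 scale: max(FC, 1/FC)."""
    return max(fc, 1.0 / fc)


def threshold_summary(results: pd.DataFrame) -> dict[str, float]:
    """Minimum magnitude fold change among passing proteins, per group tier.

    Group B pools the two- and three-replicate tiers, matching the two-row
    summary of observed minimum fold changes.  Values are ``nan`` for empty
    groups; display code rounds to 2 significant figures.
    """
    out: dict[str, float] = {}
    for name, mask in (
        ("A", results["group"] == "A"),
        ("B", results["group"].isin(["B", "B_triplicate"])),
    ):
        fc = results.loc[mask, "fold_change"]
        out[name] = float(min(magnitude_fold_change(v) for v in fc)) if len(fc) else float("nan")
    return out


def differential_union(
    results_by_comparison: dict[tuple[Tissue, Tissue], pd.DataFrame],
    focal: Tissue,
) -> set[str]:
    """Union of proteins passing in any comparison involving ``focal``."""
    union: set[str] = set()
    found = False
    for (num, den), res in results_by_comparison.items():
        if focal not in (num, den):
            continue
        found = True
        union |= set(res.index[res["group"].isin(PASSING)])
    if not found:
        raise UsageError(f"no comparisons involve focal tissue {focal.value}")
    return union


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class PairwiseDifferentialTester(BaseEstimator):
    """Differential protein-level analysis for one ordered tissue pair.

    Fitting on an imputed :class:`~lfqdiff.tables_io.IntensityTable` computes
    the replicate ln-ratios, the pooled global spread and the Group A/B
    classification.

    Parameters
    ----------
    numerator, denominator : Tissue
        The ordered tissue pair; fold changes are numerator over denominator.
    alpha : float
        Two-tailed significance level of the Group A t-test.
    spread_method : {"pooled", "all_ratios", "mean_ratios"}
        Estimator of the global ln-ratio spread (see :func:`global_spread`).
    require_common_sign : bool
        Whether Group B demands a common ratio sign across replicates.

    Attributes
    ----------
    ratios_ : LnRatioSet
    spread_ : GlobalSpread
    results_ : pandas.DataFrame
        Per-protein classification (see :func:`classify_groups`).
    """

    def __init__(
        self,
        numerator: Tissue = Tissue.CHOL,
        denominator: Tissue = Tissue.EACS,
        alpha: float = 0.05,
        spread_method: str = "pooled",
        require_common_sign: bool = True,
    ):
        self.numerator = numerator
        self.denominator = denominator
        self.alpha = alpha
        self.spread_method = spread_method
        self.require_common_sign = require_common_sign

    def fit(self, X: IntensityTable, y=None) -> "PairwiseDifferentialTester":
        self.ratios_ = compute_ln_ratios(X, self.numerator, self.denominator)
        self.spread_ = global_spread(self.ratios_, method=self.spread_method)
        self.results_ = classify_groups(
            self.ratios_, self.spread_, alpha=self.alpha,
            require_common_sign=self.require_common_sign,
        )
        return self

    def passing_counts(self) -> dict[str, int]:
        return passing_counts(self.results_)

    def threshold_summary(self) -> dict[str, float]:
        return threshold_summary(self.results_)


def run_comparisons(
    table: IntensityTable,
    pairs: list[tuple[Tissue, Tissue]],
    alpha: float = 0.05,
    spread_method: str = "pooled",
    require_common_sign: bool = True,
) -> dict[tuple[Tissue, Tissue], PairwiseDifferentialTester]:
    """Fit a :class:`PairwiseDifferentialTester` for each ordered pair."""
    fitted = {}
    for num, den in pairs:
        fitted[(num, den)] = PairwiseDifferentialTester(
            num, den, alpha=alpha, spread_method=spread_method,
            require_common_sign=require_common_sign,
        ).fit(table)
    return fitted
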