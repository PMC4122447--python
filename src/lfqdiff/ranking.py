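"""Ranked tables of up-/down-regulated proteins for a focal tissue.

A protein qualifies for the "up" (resp. "down") table when it passes the
Group A/B criteria with the focal tissue higher (resp. lower) in at least one
comparison against a reference tissue.  Rows are ordered by three keys, all
descending:

1. the number of reference tissues against which the protein passed with the
   requested direction;
2. the best group tier among those passing comparisons (A > b(t) > B);
3. the maximum magnitude fold change among the passing comparisons;

with remaining ties broken by accession, so the order is total and
reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .differential import (
    GROUP_PRECEDENCE,
    PASSING,
    magnitude_fold_change,
)
from .errors import UsageError
from .tissues import Tissue


def _oriented(res: pd.DataFrame, num: Tissue, den: Tissue, focal: Tissue) -> pd.DataFrame:
    """Return results oriented with the focal tissue as numerator."""
    if num == focal:
        return res
    if den != focal:
        raise UsageError(f"comparison {num.value} vs {den.value} does not involve the focal tissue")
    out = res.copy()
    out["mean_lnFC"] = -out["mean_lnFC"]
    out["fold_change"] = 1.0 / out["fold_change"]
    out["direction"] = out["direction"].map({"up": "down", "down": "up", "": ""})
    return out


def rank_proteins(
    results_by_comparison: dict[tuple[Tissue, Tissue], pd.DataFrame],
    focal: Tissue,
    direction: str,
    top_n: int | None = None,
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Rank proteins regulated in ``direction`` in the focal tissue.

    ``results_by_comparison`` maps ordered tissue pairs to classification
    tables (as produced by ``classify_groups``); comparisons not involving
    the focal tissue are ignored, and flipped orientations are handled by
    reciprocating fold changes.  Returns an empty table when nothing
    qualifies.
    """
    if direction not in ("up", "down"):
        raise UsageError(f"direction must be 'up' or 'down', got {direction!r}")
    oriented: dict[Tissue, pd.DataFrame] = {}
    for (num, den), res in results_by_comparison.items():
        if focal not in (num, den):
            continue
        ref = den if num == focal else num
        oriented[ref] = _oriented(res, num, den, focal)
    if not oriented:
        raise UsageError(f"no comparisons involve focal tissue {focal.value}")

    refs = sorted(oriented, key=lambda t: list(Tissue).index(t))
    rows = []
    all_accessions = sorted(set().union(*(set(r.index) for r in oriented.values())))
    for acc in all_accessions:
        key1 = 0
        key2 = 0
        key3 = 0.0
        row: dict[str, object] = {"accession": acc}
        for ref in refs:
            res = oriented[ref]
            if acc in res.index:
                rec = res.loc[acc]
                fc = float(rec["fold_change"])
                grp = str(rec["group"])
                row[f"vs_{ref.value}_fc"] = fc
                row[f"vs_{ref.value}_group"] = grp
                if grp in PASSING and rec["direction"] == direction:
                    key1 += 1
                    key2 = max(key2, GROUP_PRECEDENCE[grp])
                    key3 = max(key3, magnitude_fold_change(fc))
            else:
                row[f"vs_{ref.value}_fc"] = np.nan
                row[f"vs_{ref.value}_group"] = "none"
        if key1 >= 1:
            row.update({"key1": key1, "key2": key2, "key3": key3})
            rows.append(row)

    if not rows:
        cols = ["accession"] + [f"vs_{r.value}_{s}" for r in refs for s in ("fc", "group")]
        return pd.DataFrame(columns=cols + ["key1", "key2", "key3"])

    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["key1", "key2", "key3", "accession"],
        ascending=[False, False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    if meta is not None:
        table.insert(1, "gene_name", table["accession"].map(meta["GeneName"]).fillna(""))
    if top_n is not None:
        table = table.head(top_n)
    return table


def direction_balance(
    results_by_comparison: dict[tuple[Tissue, Tissue], pd.DataFrame],
    focal: Tissue,
) -> dict:
    """Down- vs up-regulated passing counts around the focal tissue.

    Counts each (protein, comparison) passing event once, per comparison and
    pooled; the pooled ratio is total down / total up, ``nan`` when no
    protein is up-regulated.
    """
    per_comparison = {}
    tot_up = tot_down = 0
    for (num, den), res in results_by_comparison.items():
        if focal not in (num, den):
            continue
        o = _oriented(res, num, den, focal)
        passing = o[o["group"].isin(PASSING)]
        n_up = int((passing["direction"] == "up").sum())
        n_down = int((passing["direction"] == "down").sum())
        ref = den if num == focal else num
        per_comparison[ref] = {
            "up": n_up,
            "down": n_down,
            "ratio": (n_down / n_up) if n_up else float("nan"),
        }
        tot_up += n_up
        tot_down += n_down
    if not per_comparison:
        raise UsageError(f"no comparisons involve focal tissue {focal.value}")
    return {
        "per_comparison": per_comparison,
        "up": tot_up,
        "down": tot_down,
        "pooled_ratio": (tot_down / tot_up) if tot_up else float("nan"),
    }
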