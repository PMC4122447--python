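"""End-to-end orchestration: read -> preprocess -> compare -> rank -> cluster.

``run_full_analysis`` executes the whole analysis from a single
:class:`PipelineConfig`, writes every artifact into an output directory and
returns a manifest.  Every derived constant (per-sample scale factors, the
imputation floor, each comparison's pooled sd / SEM / threshold) is recorded
in ``run_log.txt``, and re-running with identical inputs reproduces
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import preprocess, profiles, ranking, tables_io
from .differential import run_comparisons, differential_union
from .errors import LfqDiffError, UsageError, ValidationError
from .tissues import Tissue

DEFAULT_PAIRS = [
    (Tissue.CHOL, Tissue.NECK),
    (Tissue.CHOL, Tissue.TYMP),
    (Tissue.CHOL, Tissue.EACS),
    (Tissue.CHOL, Tissue.MUC),
]


@dataclass
class PipelineConfig:
    """Everything needed for one full analysis run."""

    input_path: str
    column_map: dict | None = None
    pairs: list[tuple[Tissue, Tissue]] = field(default_factory=lambda: list(DEFAULT_PAIRS))
    alpha: float = 0.05
    min_experiments: int = 2
    imputation_factor: float = 3.0
    imputation_scope: str = "global"
    spread_method: str = "pooled"
    require_common_sign: bool = True
    focal: Tissue = Tissue.CHOL
    top_n: int = 20
    cluster_min_experiments: int | None = 2
    cluster_log_profiles: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        cfg = tables_io.read_config(path)
        kwargs: dict = {}
        if "input" in cfg:
            kwargs["input_path"] = str(cfg["input"])
        elif "input_path" in cfg:
            kwargs["input_path"] = str(cfg["input_path"])
        else:
            raise UsageError("pipeline config must name an 'input' table")
        if "column_map" in cfg and cfg["column_map"]:
            kwargs["column_map"] = tables_io.parse_column_map(cfg["column_map"])
        if "pairs" in cfg:
            kwargs["pairs"] = [parse_pair(p) for p in cfg["pairs"]]
        for key in (
            "alpha", "min_experiments", "imputation_factor", "imputation_scope",
            "spread_method", "require_common_sign", "top_n",
            "cluster_min_experiments", "cluster_log_profiles",
        ):
            if key in cfg:
                kwargs[key] = cfg[key]
        if "focal" in cfg:
            kwargs["focal"] = Tissue.from_code(str(cfg["focal"]))
        return cls(**kwargs)


def parse_pair(pair: str) -> tuple[Tissue, Tissue]:
    """Parse ``"CHOL:EACS"`` into an ordered tissue pair."""
    try:
        num, den = str(pair).split(":")
    except ValueError:
        raise UsageError(f"pair {pair!r}: expected '<num-code>:<den-code>'") from None
    return Tissue.from_code(num), Tissue.from_code(den)


def run_full_analysis(config: PipelineConfig, out_dir: str | Path) -> list[str]:
    """Run every stage and return the manifest of files written (relative paths)."""
    in_path = Path(config.input_path)
    if not in_path.exists():
        raise UsageError(f"input table {in_path} does not exist")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    log_lines: list[str] = [f"input: {in_path}"]

    def _write(name: str, writer) -> None:
        writer(out / name)
        manifest.append(name)

    try:
        table = tables_io.read_intensity_table(in_path, config.column_map)
        log_lines.append(f"proteins read: {table.n_proteins}")

        overlap = preprocess.overlap_summary(table)
        pct, mean_pct = preprocess.replicate_consistency(table)

        normalizer = preprocess.EqualSumNormalizer().fit(table)
        normalized = normalizer.transform(table)
        for (exp, code), f in normalizer.scale_factors_.items():
            log_lines.append(f"scale_factor {exp}.{code}: {f:.10g}")
        log_lines.append(f"target_sum: {normalizer.target_sum_:.10g}")

        filtered = preprocess.filter_by_experiment_presence(
            normalized, config.min_experiments
        )
        log_lines.append(
            f"proteins after >= {config.min_experiments}-experiment filter: {filtered.n_proteins}"
        )
        imputer = preprocess.DetectionFloorImputer(
            factor=config.imputation_factor, scope=config.imputation_scope
        ).fit(filtered)
        imputed = imputer.transform(filtered)
        log_lines.append(f"imputation_value: {imputer.imputation_value_!r}")

        _write("normalized.tsv", lambda p: tables_io.write_intensity_table(imputed, p))
        _write(
            "overlap.tsv",
            lambda p: pd.DataFrame(
                [
                    {"statistic": "n_total", "value": overlap.n_total},
                    {"statistic": "n_at_least_two", "value": overlap.n_at_least_two},
                    {"statistic": "n_all", "value": overlap.n_all},
                ]
                + [
                    {"statistic": f"n_{e}", "value": n}
                    for e, n in overlap.per_experiment.items()
                ]
                + [
                    {"statistic": f"replicate_consistency_{t.value}", "value": v}
                    for t, v in pct.items()
                ]
                + [{"statistic": "replicate_consistency_mean", "value": mean_pct}]
            ).to_csv(p, sep="\t", index=False),
        )

        fitted = run_comparisons(
            imputed, config.pairs, alpha=config.alpha,
            spread_method=config.spread_method,
            require_common_sign=config.require_common_sign,
        )
        results = {pair: est.results_ for pair, est in fitted.items()}
        count_rows, thr_rows = [], []
        for (num, den), est in fitted.items():
            name = f"{num.value}_vs_{den.value}"
            log_lines.append(
                f"comparison {name}: sd_global={est.spread_.sd_global:.10g} "
                f"sem_global={est.spread_.sem_global:.10g} threshold={est.spread_.threshold:.10g}"
            )
            res = est.results_.copy()
            res.insert(0, "Accession", res.index)
            res.insert(1, "GeneName", imputed.meta["GeneName"])
            _write(f"{name}.tsv", lambda p, r=res: r.to_csv(p, sep="\t", index=False))
            counts = est.passing_counts()
            count_rows.append({"comparison": name, **counts})
            thr = est.threshold_summary()
            thr_rows.append(
                {
                    "comparison": name,
                    "min_fc_A": thr["A"],
                    "min_fc_A_2sf": tables_io.format_sig(thr["A"], 2),
                    "min_fc_B": thr["B"],
                    "min_fc_B_2sf": tables_io.format_sig(thr["B"], 2),
                }
            )
        _write(
            "passing_counts.tsv",
            lambda p: pd.DataFrame(count_rows).to_csv(p, sep="\t", index=False),
        )
        _write(
            "threshold_summary.tsv",
            lambda p: pd.DataFrame(thr_rows).to_csv(p, sep="\t", index=False),
        )
        union = sorted(differential_union(results, config.focal))
        _write(
            "differential_union.tsv",
            lambda p: pd.DataFrame({"Accession": union}).to_csv(p, sep="\t", index=False),
        )
        log_lines.append(f"differential union ({config.focal.value}): {len(union)}")

        for direction in ("up", "down"):
            ranked = ranking.rank_proteins(
                results, config.focal, direction, top_n=config.top_n, meta=imputed.meta
            )
            name = f"ranked_{direction}.tsv"
            if len(ranked):
                _write(name, lambda p, r=ranked: tables_io.write_results_table(r, p))
            else:
                _write(name, lambda p, r=ranked: r.to_csv(p, sep="\t", index=False))
        balance = ranking.direction_balance(results, config.focal)
        log_lines.append(
            f"direction balance ({config.focal.value}): down={balance['down']} "
            f"up={balance['up']} ratio={balance['pooled_ratio']:.10g}"
        )

        clusterer = profiles.TissueProfileClusterer(
            restrict_min_experiments=config.cluster_min_experiments,
            log_profiles=config.cluster_log_profiles,
        ).fit(imputed)
        _write(
            "profiles.tsv",
            lambda p: clusterer.profiles_.to_csv(p, sep="\t"),
        )
        _write("tree.nwk", lambda p: profiles.export_newick(clusterer.dendrogram_, p))
    except LfqDiffError:
        raise
    except Exception as exc:  # pragma: no cover - defensive context wrapper
        raise ValidationError(f"pipeline failed: {exc}") from exc

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    manifest.append("run_log.txt")
    manifest.append("manifest.txt")
    (out / "manifest.txt").write_text("\n".join(manifest) + "\n", encoding="utf-8")
    return manifest
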