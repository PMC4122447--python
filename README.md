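# lfqdiff

Label-free quantitative (LFQ) proteomics analysis for a pooled-replicate,
multi-tissue study design: cholesteatoma — a destructive keratinizing growth
in the middle ear — compared against four surrounding ear tissues (neck of
cholesteatoma, tympanic membrane, external auditory canal skin, middle ear
mucosa), with three independent mass-spectrometry experiments each measuring
one pooled sample per tissue.

The package is aimed at proteomics analysts who have protein-level MS
intensity tables (e.g. MaxQuant proteinGroups exports) from such a design
and want a reproducible, tested implementation of the whole downstream
analysis: normalization, filtering, imputation, differential statistics,
ranking, tissue clustering, and targeted-validation concordance — plus a
synthetic-data generator for calibrating and validating the statistics.

## The statistics at the core

For each ordered tissue pair, each protein *p* has per-experiment natural-log
intensity ratios on normalized, imputed intensities Î:

```
r[p,e] = ln( Î[p,e,num] / Î[p,e,den] ),   e = 1..E   (E = 3 experiments)
```

Replicate noise is pooled over **all** quantified proteins of a comparison
rather than estimated per protein:

```
sd_global  = sqrt( Σ_p Σ_e (r[p,e] − r̄[p])²  /  Σ_p (n_p − 1) )
sem_global = sd_global / √E
threshold  = 2 · sem_global          (ln units)
```

Two tiers of differential proteins are called:

* **Group A** — quantified in all E experiments, two-tailed one-sample
  t-test of the ln-ratios against 0 with p < 0.05, and |mean ln-ratio| >
  threshold;
* **Group B** — tested only on A-failures: every single replicate's
  |r[p,e]| > threshold with a common sign (≥ 2 replicates; all-E Group B
  proteins are flagged `b(t)`).

No multiple-testing correction is applied beyond this combined t +
fold-change rule (see `docs/methods.md`). Upstream, each (experiment,
tissue) sample is scaled to the grand-mean summed intensity,
single-experiment identifications are dropped, and zeros (non-detections)
are replaced by 3× the lowest positive intensity of the dataset. For a
tissue-level overview, per-protein relative profiles (tissue level divided
by the across-tissue mean) are clustered with distance 1 − Pearson
correlation and average linkage.

## Worked example

```sh
lfq-tissuediff simulate --seed 7 --n-proteins 400 --out synthetic.tsv --truth truth.tsv
printf 'input: synthetic.tsv\n' > pipeline.yaml
lfq-tissuediff run --config pipeline.yaml --out results
cat results/passing_counts.tsv
```

prints (for this seed):

```
comparison      A       B       total
CHOL_vs_NECK    30      7       37
CHOL_vs_TYMP    36      10      46
CHOL_vs_EACS    35      8       43
CHOL_vs_MUC     32      9       41
```

i.e. per pairwise comparison of cholesteatoma (CHOL) against each reference
tissue, the number of Group A proteins (all-replicate, t-test significant,
mean fold change above 2×SEM), Group B proteins (every replicate above the
threshold, consistent sign) and their total. The run log records every
derived constant, e.g. for CHOL vs EACS
`sd_global=1.202 sem_global=0.694 threshold=1.388` (so a protein needs a
mean fold change beyond e^1.388 ≈ 4.0× to pass Group A), and
`results/tree.nwk` holds the tissue dendrogram:

```
(Cholesteatoma:1.33,(('Neck of cholesteatoma':1.14,'Middle ear mucosa':1.14):0.067,
 ('Tympanic membrane':1.15,'External auditory canal skin':1.15):0.053):0.12);
```

`results/ranked_up.tsv` / `ranked_down.tsv` list the top proteins sorted by
(number of reference tissues passed with that direction, best group tier,
maximum magnitude fold change). The same stages are available as library
calls (`normalize_equal_sum`, `PairwiseDifferentialTester(...).fit(table)`,
`TissueProfileClusterer(...)`, …) and as the subcommands `preprocess`,
`compare`, `rank`, `cluster`, `simulate`, `validate`, `convert-xlsx`.

Real study tables arrive as workbooks; convert and map their columns once:

```sh
lfq-tissuediff convert-xlsx --in table.xlsx --out table.tsv
# then supply a column_map in YAML: {column name: "<experiment>:<tissue-code>"}
```

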