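# Methods

This note documents the models, defaults and design choices behind
`lfqdiff`, and what the synthetic-data experiments do and do not establish.

## Study design and data model

The analysis targets a pooled-replicate, five-tissue design: three
independent LC-MS/MS experiments, each quantifying one pooled sample per
tissue (cholesteatoma, neck of cholesteatoma, tympanic membrane, external
auditory canal skin, middle ear mucosa). The unit of data is a protein ×
(experiment, tissue) table of nonnegative MS intensities in arbitrary
units; a zero encodes non-detection in that sample. Because the tissues
within an experiment come from the same pooled patient set, tissue
contrasts are paired within experiment, and the experiment is the replicate
unit (E = 3).

## Preprocessing

**Normalization.** Each (experiment, tissue) sample is scaled so its summed
intensity equals the grand mean of the original per-sample sums. Equal-sum
(total-intensity) normalization presumes the bulk of the proteome is
comparable across samples; the target was chosen as the grand mean — rather
than an arbitrary constant — so the data keep their original scale and all
samples are treated symmetrically. Within-sample ratios are untouched.

**Presence filter.** Proteins identified (nonzero in ≥ 1 tissue) in fewer
than 2 of the 3 experiments are removed: they carry no replicate
information for the ratio statistics. "Detection" always means strictly
positive intensity.

**Imputation.** Remaining zeros are replaced by `factor × min`, with
`factor = 3` and `min` the lowest positive intensity of the whole
normalized, filtered dataset. The floor makes ratios against
below-detection-limit values finite while marking them as extreme; taking
the minimum globally (one dataset-wide constant) is the default, with a
per-experiment variant exposed (`scope="experiment"`) because the stage
order makes either reading defensible. The stage order is fixed as
normalize → filter → impute so the floor reflects the analyzed dataset.
The pre-imputation detection pattern is preserved in the table's `detected`
mask and drives all presence-based statistics downstream.

**Identification statistics.** Overlap counts (total, ≥ 2 experiments, all
experiments, per experiment) come from the detection mask. Replicate
consistency restricts to proteins identified in all experiments and asks,
per tissue, what fraction of the proteins ever detected in that tissue were
detected there in *every* experiment; the per-tissue denominators (rather
than one global denominator) make the statistic insensitive to proteins
genuinely absent from a tissue.

## Differential statistics

Per ordered tissue pair, ln-ratios `r[p,e] = ln(Î_num/Î_den)` are computed
within experiment on imputed intensities. A replicate contributes no ratio
when the protein was undetected in both tissues of that experiment (an
imputed-over-imputed ratio is meaningless), and a protein enters the
comparison only with ≥ 2 defined replicates.

**Global spread.** The differential threshold is 2 × a *global* SEM: with
only three replicates, per-protein variance estimates are unstable, so
replicate variation is pooled across all quantified proteins of the
comparison. The default estimator is the pooled within-protein standard
deviation

    sd_global = sqrt( Σ_p Σ_e (r[p,e] − r̄[p])² / Σ_p (n_p − 1) ),

i.e. exactly the replicate-noise component, free of between-protein effect
variance; `sem_global = sd_global/√E` and `threshold = 2·sem_global`. Two
alternative readings are exposed (`spread_method="all_ratios"`: SD of all
ln-ratios; `"mean_ratios"`: SD of per-protein mean ratios) because the
phrase "global standard error" does not pin down the algebra; the pooled
form is the default because the SEM of a protein's fold change is a
replicate-noise quantity. Adjudicating among the variants against the
originating study's summary table requires its deposited data
(see `tests/test_acceptance.py`).

**Two-tier classification.** Group A requires all E replicates, a two-tailed
one-sample t-test of the ln-ratios against 0 with p < α (default 0.05) and
|mean ln-ratio| > threshold. Only A-failures are tested for Group B: every
defined |r[p,e]| > threshold with a common sign; Group B proteins with all E
replicates are labelled `b(t)`. The one-sample-on-ratios form (df = n−1) is
the paired-design reading of the tissue contrast; a two-sample test on
intensities would ignore the within-experiment pairing. The common-sign
requirement is the default (a magnitude-only switch exists). Degenerate
zero-variance ratio vectors get p = 0 when the mean is nonzero and p = 1
otherwise; the direction is undefined for an exactly zero mean.

**No multiple-testing correction** is applied beyond the combined t +
fold-change rule. This is a deliberate property of the implemented
procedure: the two-tier filter controls, but does not formally bound, the
false discovery rate — the null simulation below quantifies its per-protein
error rate, and the recovery experiment shows the realized FDR depends on
the proportion of truly changed proteins. FDR-controlling alternatives are
out of scope by design.

**Summaries.** Passing counts report |A|, |B ∪ b(t)| and their total; the
threshold summary reports, per tier, the minimum magnitude fold change
max(FC, 1/FC) among passing proteins (display-rounded to 2 significant
figures); the differential union collects proteins passing in any
comparison involving the focal tissue; fold changes are reported as
exp(mean ln-ratio), serialized to 3 significant figures in display tables
and at full precision in machine-readable ones.

## Ranking

Up-/down-regulated tables for the focal tissue sort qualifying proteins by
(1) the number of reference tissues against which they passed with the
requested direction, (2) the best tier among those passes (A > b(t) > B),
(3) the maximum magnitude fold change among the passes, with residual ties
broken by accession so the order is total. Key 1 counts *passing*
comparisons, not mere sign agreement — the stricter reading. Exact
reproduction of any particular published table ordering is a non-goal: the
three keys do not uniquely determine an order.

## Profiles and clustering

Relative profiles L[p,t] divide a protein's per-tissue mean (over
experiments) by its across-tissue mean, so each profile averages to 1. The
clustering population is the ≥ 2-experiment proteins with no fold-change
criteria applied — the overview is deliberately independent of the
differential filter. Tissues are clustered on 1 − Pearson correlation of
their profile columns with unweighted average linkage (UPGMA); linear L is
the default (an ln-L switch exists). Equal minimum distances resolve by the
tissue enum order of the input, making trees deterministic. Merge heights
are checked to be nondecreasing; average linkage does not guarantee
ultrametricity in general, and no stronger property is asserted. Trees are
serialized as Newick with branch lengths from merge-height differences.

## Validation concordance

Targeted (SRM) follow-up is consumed as one summarized record per protein
(mean ln fold change, p-value); per-sample SRM statistics are upstream of
this package. Verdicts: `confirmed` (p < 0.05, sign agrees with discovery),
`qualitative` (0.05 ≤ p < 0.15, sign agrees), `unconfirmed` (sign mismatch
at any p, or p ≥ 0.15), `not_detected` (missing SRM values). Sign agreement
alone operationalizes "in line with discovery"; an optional magnitude floor
(`min_abs_lnfc`) is off by default since no cutoff is inherent to the rule.
`srm_validation_panel()` ships a qualitative encoding of the
cholesteatoma-vs-skin validation panel: per protein only the direction and
outcome band are meaningful; the numeric values are synthetic placeholders
within each band.

## Synthetic data

The generator produces `I[p,e,t] = exp(base_p + effect_{p,t} + ε_{p,e,t})`
with Gaussian protein baselines, per-tissue planted effects (so all pairwise
true ln fold changes are mutually consistent) and Gaussian replicate noise,
followed by intensity-dependent dropout: each entry is zeroed with
probability `sigmoid((midpoint − ln I)/scale)`, reproducing
missing-at-low-abundance. Defaults: 2400 proteins, E = 3, baseline ln-mean
16 and ln-sd 2 (a wide MS dynamic range), replicate noise sd 0.6 in ln
units — chosen so per-comparison 2×SEM thresholds land around ln 2–ln 3, the
range of the minimum passing fold changes such designs report — and dropout
midpoint 11.5 (≈ 2.25 baseline sd below the median protein), which yields
per-tissue replicate consistency near 90%. `study_like_config` plants
effects on ~15% of proteins in the focal tissue (4:1 down:up, |lnFC|
uniform on [ln 2, ln 50]) plus a 2% contingent per reference tissue.

What the generator does **not** emulate: experiment-level correlated
missingness (a protein absent from an entire experiment's run), peptide- to
protein-level roll-up artifacts, shared-peptide protein grouping, intensity
saturation and batch drift. In particular, because dropout is independent
per sample, the generator cannot simultaneously match a real study's
experiment-overlap fractions and its per-tissue replicate consistency;
passing synthetic tests therefore validates the statistical machinery, not
the generator's fidelity to any specific instrument's missingness.

## Calibration and recovery experiments

* **Null calibration** (10,000 proteins, noise sd 0.6, no effects, no
  dropout): the one-sample t-test is exact under Gaussian noise, so its
  rejection rate must sit within 3 binomial standard errors of α; the full
  Group A rule, which adds the 2×SEM mean criterion, passes strictly fewer
  (≈ 1%).
* **Recovery** (2,000 proteins, 800 sign-balanced planted effects of
  |lnFC| = ln 10 in the focal tissue, noise sd 0.1, no dropout):
  sensitivity ≥ 0.99 and FDR ≤ 0.05. The classification runs on the
  generated table without equal-sum renormalization: planting many large
  one-sided composition changes deliberately violates the equal-sum
  assumption (the real design equilibrates loaded protein amounts
  upstream), and renormalizing such data would shift every null protein's
  ratio — the experiment isolates the differential machinery. The planted
  fraction (40%) was set from the analytic false-positive rate of the
  uncorrected rule (≈ 1–2% per comparison): with uncorrected per-protein
  tests, a realized FDR ≤ 0.05 requires a substantial true-effect prior;
  this is a property of the procedure, not of the implementation.
* **Oracle agreement**: the vectorized classifier is checked against an
  independent straight-line restatement of the rules on 1,000 random small
  tables, and the tissue dendrogram against an exhaustive average-linkage
  agglomeration on a fixed 6-protein instance.

Problem sizes throughout (≤ 10,000 proteins, ≤ 1,000 replicate tables) keep
the whole suite and the acceptance script to seconds on one CPU while
leaving binomial standard errors small enough for the stated bands.

## Numerical conventions and degenerate inputs

Equal-sum conservation is asserted to 1e-9 relative spread; profile row
means to 1e-9; imputation is idempotent by construction. All-zero samples,
all-zero tables, zero-variance tissue profiles, empty results tables,
duplicate accessions and negative intensities are rejected with named
errors rather than propagated. Pipeline outputs are byte-deterministic:
floats are serialized with fixed formats (`%.17g` for intensities, which
round-trips doubles; `%.10g` in logs; 3 and 2 significant figures in
display tables), and every derived constant is logged.

## Known limitations

* The pooled-spread default cannot be adjudicated against the originating
  study's published per-comparison minima without its deposited data; all
  three spread variants are first-class options.
* Ranking reproduces key structure, not any specific published row order.
* The concordance module treats SRM p-values as given; it implements no
  targeted-MS statistics of its own.
* With E = 2 surviving replicates a protein can never reach Group A; this
  is inherent to the tiered design, not a defect.
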