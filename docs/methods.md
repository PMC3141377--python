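# Methods

## The question the pipeline answers

Two samples of the same tumor, processed differently, give different
expression signatures. Macrodissection keeps 40–50% stroma; LCM
isolates epithelium but needs a second round of T7 amplification that
silences a substantial fraction of transcripts. `stromasig` measures
the downstream consequence: which classes of genes (amplified,
deleted, known over-/under-expressed) each processing method can still
detect as differentially expressed between cancer and normal tissue.

## Differential expression

Per gene, a two-sided two-sample t-test on log2 intensities between
the cancer and normal classes. Welch's unequal-variance form is the
default because the design is unbalanced (20 tumors vs 6 normals) and
tumor variance is typically larger; a pooled-variance option exists
because classic array tools default to it. The two give identical
results on balanced equal-variance inputs (the worked 3-vs-3 example
yields t = −4.899 on 4 df, p ≈ 0.0081 either way). P-values are
floored at 1e-16 so the LS log transform stays finite; genes constant
everywhere get p = 1. Fold changes are computed from arithmetic means
of log2 values (i.e., geometric means of intensities) and reported in
the signed convention: r = 2^(Δlog2), printed as −1/r when r < 1.
Signatures are raw-threshold selections (p < 1e-6 for signature
tables, p < 0.05 for member reporting) with no multiplicity
correction, matching how such feature lists are conventionally
printed; the LS test, not the per-gene threshold, carries the
inference.

## The LS statistic and its null

LS = mean(−ln p) over the set members present in the analyzed
universe; the summary statistic is mean(ln p). The null is gene
resampling: R sets of N genes drawn uniformly *without replacement*
from the full universe (not from any DE-filtered subset), and
LS P = #{summary_random ≤ summary_observed} / R.

Numerical choices that matter:

* **Ties count as extreme** (`≤`). This makes the test conservative,
  fixes the degenerate whole-universe set at P = 1, and gives the
  exact-vs-Monte-Carlo comparison a clean convention.
* **Summation order.** Random subset means are computed over indices
  sorted ascending, the same order used for the observed statistic, so
  that a random draw of the observed set ties it exactly in floating
  point rather than landing an ulp away.
* **P = 0 is stored as 0.0** and displayed as `< 1/R`; no +1
  pseudo-count is added.
* **Per-set child seeds.** A master seed is XORed with a CRC32 of the
  (method, set-name) labels, so adding or removing a gene set never
  perturbs any other cell's resampling stream, and every cell is
  reproducible from its recorded seed. Derived seeds stay below 2³¹.
* An exhaustive enumerator over all C(U, N) subsets serves as the
  exact reference for small universes; the Monte-Carlo path is held to
  within 3 binomial SDs of it in the acceptance suite.

Because two-sided p-values make LS direction-blind, direction
composition is reported separately (member partition with fold-change
signs); the partition classifies each member as detected by both
methods, micro only, macro only, neither, or unmapped.

## Copy-number sets

The proprietary ADM-2 caller is out of scope; the stand-in is a
same-sign run caller: maximal runs of consecutive probes with
|log2| ≥ 0.25 (half the retention amplitude) and one sign, retained
under the study's printed filters — ≥ 5 probes, mean |log2| ≥ 0.5
(inclusive), ≤ 10⁶ aberrations, largest |mean| first. Precomputed
segments can be supplied instead. Per-gene log2 is the mean of probes
overlapping the gene (closed intervals, 1-based); the probe→gene
summarization of the original tooling is not documented anywhere, so
the simplest defensible rule is used. Gene-set membership is strict:
log2 > +0.5 (gain) or < −0.5 (loss) in ≥ 1 of the patients; a gene may
appear in both sets via different patients. BED input is converted
from 0-based half-open to 1-based inclusive on read.

## Synthetic cohort generator

The generator is the package's study stand-in, since no comparable
paired macro/micro dataset is deposited. Per gene g and tumor t:

    E(g,t) = baseline(g) + z(g,t)·effect(g) + dose·seg_log2(g,t) + ε
    S(g,t) = baseline(g) + stromal_boost(g) + ε
    macro(g,t) = log2( π_t·2^E + (1−π_t)·2^S )
    micro(g,t) = log2( π_micro·2^E + (1−π_micro)·2^S ), then floored to
                 0 with probability 0.30 per cell
    normal(g,n) = baseline(g) + ε

RNA mixes on the linear intensity scale (physical mixing), even though
all I/O is log2. Dropout is a collapse to a floor (log2 = 0), not
multiplicative attenuation, because amplification transcript loss
manifests as absent calls. Macro purity π_t is Beta-distributed,
moment-matched to median 0.60 with IQR 0.60–0.725; LCM purity is fixed
at 0.95 (the micro arm uses the same mixture formula so that the
purity parameter is meaningful rather than decorative).

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| n_tumor / n_normal | 20 / 6 | the emulated design (normals pooled, 3 per method) |
| n_genes | 2,000 | desk scale; the statistics do not need a 22k-probe array |
| purity_macro median (IQR) | 0.60 (0.60–0.725) | post-macrodissection tumor-nuclei figures |
| purity_micro | 0.95 | near-pure LCM epithelium |
| dropout_rate | 0.30 | reported transcript loss of the extra amplification round |
| effect_log2 | U(1, 5) | matches the 2- to 38.5-fold range of the printed signature tables |
| noise_sd_log2 | 1.25 | combined biological + technical within-class SD typical of clinical tumor arrays |
| effect_penetrance | 0.5 | intra-tumor heterogeneity: half the tumors deregulate a given signature gene (most of the cohort is diffuse-type, i.e., scattered tumor cells) |
| n_up / n_down / n_stromal | 60 / 60 / 150 | signature sets sized like the 58/66-gene literature sets; a generous stromal program (collagens, ECM, immune) |
| cn genes | 30 gain + 30 loss in 10-gene amplicons, carrier prob 0.3 | a few recurrent amplicons per genome, each in a handful of patients |
| segment amplitude | U(0.55, 1.5) | detectable under the retention filters with margin |
| cn_dose_coefficient | 1.0 | expression follows dosage one-to-one on the log2 scale |

The noise SD and penetrance were fixed once, during model design,
at values for which the generator reproduces the qualitative
phenomenon it exists to emulate — macro detects gains/up-signature,
micro detects losses/down-signature, cross cells null — robustly
across seeds. The mechanism is not hand-painted into the outputs: it
emerges from the mixture (stroma and entrapped normal epithelium mask
down-regulation at 60% purity) and from the dropout floor (a 30%
collapse to 0 pulls tumor means down by ~0.3·baseline, cancelling
typical up-regulation but reinforcing down-regulation, while
inflating the competitive null for every gene).

What the generator does **not** emulate: probe-level hybridization
and MAS5 present/absent calls, batch and scanner effects, correlated
gene programs (genes are independent given their role), chromosomal
position effects on expression beyond the planted amplicons, and
realistic LCM dropout, which in real data is intensity-dependent
rather than uniform. Consequently a passing pipeline demonstrates
that the statistics behave correctly under this mixture-plus-dropout
model — not that real macro/micro data would show effects of the same
magnitude. One visible artifact: the synthetic cross-method Pearson
correlation (median ≈ 0.31) is well below the ~0.75 seen on real
paired samples, because the floor-at-0 dropout produces far harsher
outliers than real amplification loss; the correlation is therefore
validated as a monotone property (it rises with purity and falls with
contamination), not as a fixed value.

## Pipeline and report

For each method the tumor matrix is combined with the pooled 6-sample
normal class (an option restricts each method to its 3 method-matched
normals, since pooling mixes two technical regimes); DE runs once per
method, and every (method × set) cell gets an LS test against that
method's full gene universe. Sets with no universe overlap become NA
cells with a reason rather than aborting the run. The report carries
the grid, per-patient cross-method correlations (median, IQR), member
partitions, and run metadata (seeds per cell, R, version), and is
written as TSV + JSON + a plain-text summary.

## Problem sizes in the test and acceptance suites

Unit tests run on 200–400-gene cohorts; the calibration and asymmetry
checks use the full default configuration (2,000 genes, 20 + 6
samples) with R = 10,000 resamples and 10 master seeds, and the
Monte-Carlo/exact comparison uses R = 50,000 on ≤ 12-gene universes —
sizes at which every statistical property of interest is already
exercised while the whole suite stays fast on one CPU.

## Known limitations

* The LS test inherits the gene-sampling null's assumption of
  exchangeable genes; inter-gene correlation (real co-expression)
  makes it anti-conservative, as for all gene-resampling set tests.
* The run-based segment caller is not ADM-2; on noisy real profiles
  the two will disagree near threshold. Precomputed segments bypass
  it.
* Probe-set-to-symbol collapsing is externalized (ProbeGeneMap TSV);
  analyses default to symbol level.
* With R resamples the smallest nonzero LS P is 1/R; choose R
  accordingly when very small P values matter.
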