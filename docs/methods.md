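# Methods

This note documents the models, estimators and defaults implemented in
`quantgut`, the assumptions behind them, and what the synthetic-data tests
do and do not demonstrate about real data.

## Load estimators

**qPCR.** Each run carries its own standard-dilution series; the curve
`Cq = b + m·log10(copies)` is fit by ordinary least squares, and amplification
efficiency is reported as `10^(−1/m) − 1` (so m = −3.3219 ⇔ 100%). Samples
are quantified at the mean of their triplicate Cq after dropping wells
flagged "no amplification"; if two or more of three wells are missing the
sample is reported below the detection limit (the aggregation rule is a
package choice — assays rarely document theirs). The 95% CI uses the
Student-t quantile with df = n−1 (a z-quantile badly under-covers with
n = 3) and adds the calibration curve's prediction variance at the
back-calculated point in quadrature. With 7 standards and Cq SD 0.15 this
yields slightly conservative (~99%) empirical coverage; we prefer that to
the ~81% coverage of the naive z-interval.

**ddPCR.** The standard partition model: droplet occupancy is Poisson, so
`λ = −ln(negative fraction)` copies per droplet. Droplet volume defaults to
0.85 nL (vendor convention; configurable). Runs with every droplet positive
are flagged `above_range`; runs with fewer than 3 positive droplets are
flagged `below_llod` (the package's LLOD convention for this assay). The CI
is a Wilson interval on the negative fraction pushed through −ln; empirical
coverage ≈ 95%.

**MPN.** The likelihood for a replicated serial dilution with `p_i` of
`n_i` wells positive at delivered volume `v_i` is maximized by a bracketed
root search on the score function (monotone in λ), to relative tolerance
1e−12; a dense grid-search oracle agrees to < 0.01%. The CI is log-normal
on ln λ with the observed Fisher information `I(λ) = Σ n_i v_i² e^{−λv_i} /
(1 − e^{−λv_i})`. No small-sample bias correction is applied; the cited
macro-based calculators are likewise plain ML. Under the study design —
two series of eight consecutive ten-fold dilutions, 10 μL inocula, eight
wells per dilution — the estimator is intrinsically coarse: σ(log10 MPN) ≈
0.2, i.e. a *median* relative error near 30% even though CI coverage is
nominal (~94–95%). This is a property of the design, not of the solver;
callers needing < 10% error from MPN would require many more replicate
wells per dilution.

**Normalization.** Lumenal contents are reported per gram via the recorded
extraction chain (default: 0.05 g into a 100 μL eluate); mucosa per 100 ng
of input DNA; MPN per mL of homogenate, convertible to per gram through the
homogenate volume.

## Absolute profiling

Relative abundances are the per-sample closure of the count table;
all-zero samples are flagged and excluded. Absolute abundance is
`fraction × total load`; a cell is flagged below the LLOD when it falls
under the load-equivalent of one read at that sample's depth (configurable
floor). Zeros stay zero — pseudocounts exist only inside the CLR transform.

Contaminant identification uses two rules, prevalence first:

1. a taxon with zero counts in every cecum-contents sample (the
   highest-biomass compartment) but reads elsewhere;
2. a frequency score: for each taxon, log frequency is regressed against
   log DNA concentration under a contaminant model (slope fixed at −1,
   as implied by a constant ambient mass per reaction) and a biological
   model (constant frequency); the score is
   `SSR_contam / (SSR_contam + SSR_biol)` and taxa below 0.5 are flagged.
   The score needs ≥ 5 samples with non-zero frequency. The 0.5 default is
   the score's symmetry point.

Removal drops columns; relative tables are re-closed, absolute tables are
**not** rescaled (removing a contaminant subtracts mass). A switch retains
plant-organellar taxa (chloroplast / Rickettsiales-mitochondria), which are
real dietary signal rather than reagent contamination even though their
frequency also scales inversely with microbial load. Taxonomic collapse
groups lineage prefixes through the requested rank, keeping placeholder
ranks so ASVs unassigned below some rank group under their deepest assigned
prefix.

## Functional scaling

The package consumes per-ASV predicted gene copies and 16S copy numbers
(PICRUSt2-style hidden-state output); it does not re-implement the
prediction. The added arithmetic is exact: genome equivalents are absolute
16S copies divided by per-genome 16S copies, and ortholog abundance is the
genome-weighted sum of per-genome gene copies. KO identifiers are data, not
constants.

## Bile acids

Peak areas are processed in four steps. (1) Drift correction: per species,
a piecewise-linear factor through the pooled-QC injections (QC area /
first-QC area), with edge-holding outside the QC bracket; a global
polynomial would assume more about the drift than the every-eight-injections
QC cadence supports. (2) Calibration: 7 levels, 0.05–30 μM, three series
pooled, **1/x-weighted** least squares on the IS-normalized response. The
weighting matters: with approximately multiplicative detector noise,
unweighted OLS lets the 30 μM standards set the intercept to ±0.2 μM, which
multiplies small concentrations several-fold; 1/x weighting is the standard
bioanalytical choice for a 600-fold range. (3) Quantification: inverse
calibration, LLOQ = lowest calibration level (0.05 μM; below → 0 with a
flag), above-range values reported but flagged; the UDCA/HDCA epimer pair is
reported as a sum (they co-elute); sample-level units follow the dilution
chain — nmol/g for contents (×100 chain), μM for bile (×10 ethanol, ×10
water, then the ×100 chain). Internal-standard normalization applies where
a matched D4 standard exists; the 9-standard → 27-analyte mapping ships as
an editable TSV registry alongside each species' conjugation (tauro / glyco /
unconjugated) and primary/secondary class. The merged UDCA/HDCA record is
classified secondary. (4) Summaries: total pool, fraction unconjugated,
fraction of secondary species (conjugated + unconjugated).

## Statistics

CLR uses the dataset's minimum non-zero value as the pseudocount, added to
zero cells only, rows re-closed before `ln(x) − mean(ln x)`.
Log10-standardization replaces non-positive cells with a floor (default:
the table's minimum non-zero value), then z-scores per feature with the
sample SD (n−1); zero-variance features are dropped with a warning. PCA
(full SVD) applies a deterministic sign convention: the largest-magnitude
loading of each component is positive. Group comparisons: Kruskal–Wallis
omnibus with tie correction, pairwise two-sided Wilcoxon–Mann–Whitney —
exact when both groups have n ≤ 8 (the study's n = 6), asymptotic with
continuity correction otherwise — and Benjamini–Hochberg adjustment across
the pairwise family per feature. Load correlations are Pearson on log10
loads (the natural scale for quantities spanning decades).

## The synthetic-data model

The generator draws, per sample: a total microbial load (log-normal, with
group × site means ~3 log10 lower in the TC-F upper gut and equal in the
lower gut); per-taxon log-normal propensities closed to fractions, with
three behaviors — *fecal* taxa set to exactly zero in the TC-F upper gut
(so LLOD flagging is testable), *true small intestine* taxa unchanged
across groups, *cecum-shifted* taxa reduced 1 log10 in the TC-F cecum only;
a constant dietary organellar 16S level (~10^6.5 copies/g chloroplast,
10^6 mitochondria) independent of microbial load; and reagent contaminants
as fixed ambient copies per sequencing reaction, which produces the
inverse-frequency signature mechanically. Counts are multinomial at the
configured depth (Dirichlet-multinomial overdispersion available, off by
default — no count-noise model is implied by the data the design emulates;
an `expected` mode emits exact real-valued expected counts for identity
tests). Assay design constants mirror the study: triplicate qPCR with a
7-point decade standard series; ddPCR with 20,000 droplets of 0.85 nL and
bench-style auto-dilution into the quantifiable range; MPN with 8 ten-fold
dilutions × 8 wells × 10 μL; bile-acid runs with QC every 8 injections,
three calibration series, 5 μM internal standards, linear sensitivity
drift and 5% log-normal area noise. Bile-acid pools use per-group × site
totals (highest in the small intestine, ~10× lower in the large intestine),
an unconjugated fraction rising SI1 → SI3 in coprophagic groups but ~0.01
in TC-F, and a secondary fraction lower in TC-F; per-taxon effect sizes are
not published numerically anywhere, so these defaults were chosen once to
reproduce the qualitative patterns at realistic magnitudes.

One shared generator is seeded from the config; per-sample generators are
derived deterministically, so identical seeds give bit-identical studies.

**What passing tests show — and don't.** Recovery and direction tests
demonstrate that the estimators and the pipeline are correct and well
calibrated *under this generative model*: multinomial counts, log-normal
loads, exactly linear assay responses, a known contaminant mechanism. Real
amplicon data add PCR and extraction biases, taxon-correlated
overdispersion, chimeras and index hopping; real LC-MS adds matrix effects
and nonlinear saturation. None of those are simulated, so green tests here
validate the computations, not the upstream chemistry.

## Problem sizes used in validation

The validation suite (and `scripts/acceptance.py`) uses: 1,000 random MPN
plates for the oracle comparison; 500 simulated assays per decade over
10²–10⁹ for recovery; one full study (144 content samples, depth 10⁴) for
profile recovery; 200 replicate studies for contaminant-filter power;
1,000 null replicates × 8 features for FDR calibration; and 100 replicate
studies for the four direction tests — sizes at which every stochastic
metric is stable to well under its test margin.

## Known limitations

* MPN accuracy is design-limited (see above); the estimator reports honest
  CIs rather than pretending to precision the plate cannot deliver.
* The frequency score assumes contaminant mass per reaction is constant;
  batch-varying contamination would need per-batch scoring.
* Inferred gene content is exactly that — inference from marker genes; it
  says nothing about expression or enzyme activity.
* Bile-acid quantification trusts the supplied peak areas; no peak-quality
  re-assessment is attempted.
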