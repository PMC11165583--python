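# Methods

This note records the models behind `plasmatrace`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter when reading results.

## Concentration calibration

LFQ intensity is treated as proportional to plasma concentration up to a
power law, i.e. linear on the log10–log10 scale. The model

    log10(c mg/dL) = intercept + slope · log10(LFQ)

is fitted by OLS on the anchor panel, pairing each anchor's **median over
samples** of log10 LFQ with its log10 reference concentration. The median
(not the mean) keeps anchors that are themselves acute-phase responders
(HP, SERPINA1, TTR) essentially at their baseline value as long as fewer
than half of a donor's samplings fall in an episode. Regression direction
is concentration-on-LFQ, so the fitted map applies directly to new
quantities. Log base 10 is used throughout.

Anchors absent from a table are skipped with a warning; non-positive
median quantities exclude an anchor; fewer than 3 usable anchors is an
error. R² is reported but not gated: with 22 anchors spanning five orders
of magnitude R² ≈ 1 whenever the data are sane.

The bundled reference table lists typical adult plasma reference-interval
midpoints for the 22 anchors, compiled from standard clinical-chemistry
literature (e.g. A2M 200, HP 100, SERPINA1 150, TTR 25, F8 0.015 mg/dL).
These values are a calibration convention, not a measurement made here;
`--refs` accepts any user table with the same two columns.

## Report ingest

The native report dialect is a TSV with `protein_group`, `run`,
`quantity`, `q_value`; a mapping layer accepts DIA-NN-style column names
(`Genes`, `Run`, `PG.Quantity`, `PG.Q.Value`). Records with q-value above
1% are dropped at read time; the threshold is inclusive (q ≤ 0.01 kept),
a convention choice since "1%" alone does not fix the boundary. Injection
replicates collapse to their per-protein median. Missing quantities are
absent records, never zeros — downstream code decides how to treat
absence. Keratins and immunoglobulin variable-region entries are removed
by id pattern as contaminant classes.

## Covariation clustering

Protein distances are 1 − Pearson correlation of the z-scored log10
trajectories. Correlation distance was chosen over Euclidean because the
quantity of interest is the *shape* of a trajectory, not its magnitude:
two chains of one complex at different absolute abundances should sit at
distance ~0. z-scores are computed on log10 concentrations so multiplicative
responses of very different magnitude (a 50-fold CRP spike vs a 2-fold HP
rise at the same episodes) standardize to comparable profiles. Rows whose
log-trajectory is constant (within float jitter, sd ≤ 1e-10·(1+|mean|))
carry no signal and are excluded with a warning; with missing values,
correlations are pairwise-complete with a minimum overlap of 3 samples.

Sample distances are 1 − Pearson over the protein dimension of the
**log10 concentrations without z-scoring**: a sample's proteome profile is
its abundance pattern across proteins, and per-protein standardization
would erase exactly the shared structure that makes two proteomes alike
(it would leave only measurement noise for every non-responding protein).

Agglomeration is complete linkage (scipy), leaves pre-sorted
lexicographically so tied merges resolve deterministically; merge heights
are monotone by construction. Cluster extraction at a cut height takes
connected components of merges **strictly below** the height, so a cut at
0 yields singletons. The default cut is 0.3, with 0.1 the conventional
"tight cluster" reading (stoichiometric complexes). Trees export to
Newick via scikit-bio.

## APR detection and APP classification

Peaks: per hallmark (CRP, SAA1, SAA2), each time point's fold over the
donor's median hallmark level is computed; the composite fold is the
median across hallmarks, and a time point is a peak when the composite
exceeds 5×. The median-over-all-time-points baseline is robust as long as
peaks are a minority of samplings, which holds for designs with ≤ 2
episodes over ≥ 5 points. The 5× rule is a package convention — episodes
in such data are unambiguous (hallmarks rise 10–100×), so the exact value
is uncritical; it is configurable.

Baseline time points are those neither peaks nor peak-adjacent; for
patient donors T0 is additionally excluded by default because
pre-transplant profiles are systematic outliers. Fold change is peak
concentration over baseline median, maximized over peaks for the positive
call and minimized for the negative call. Classification requires both
the ≥ 25% change (the APP definition) and trajectory agreement with the
mean hallmark z-composite, |r| ≥ 0.6 with matching sign — the testable
form of the "mirror images" behavior of negative APPs. Classification is
scale-invariant.

The APOA/SAA ratio treats missing members as 0 and returns NaN where the
SAA sum is 0 (healthy donors can have SAA below detection).

## SEC complexome profiling

The fraction↔MW map is log-linear, fitted by OLS on the six standards'
known MWs vs observed peak fractions; the void marker is never fitted. A
non-negative slope is rejected outright (wrong column orientation);
non-monotone calibrant ordering warns and reports residuals so users can
judge mild nonlinearity of dual-column setups. The valid range defaults
to 10–3000 kDa.

Apparent MW: the main peak is the contiguous run of retained fractions
around the global maximum with intensity ≥ 10% of the maximum; the
calibration is applied to the intensity-weighted centroid of that window.
A mode (argmax) estimator is available behind a flag. Secondary
above-threshold peaks are reported as a list but never set the apparent
MW (e.g. AMBP appears both in IαI and in other assemblies). Excluded
fractions are omitted, not interpolated — matching the practice of
removing poor-quality fractions — which can bias a centroid near an
exclusion by up to about one fraction-width.

Coelution: Pearson correlation over ≥ 4 shared retained fractions. Groups
are connected components of the graph linking pairs with score ≥ 0.9 and
apparent MWs within 20% (relative to the larger); group MW is the median
member apparent MW. Note SEC cannot distinguish co-complexed proteins
from independent species of indistinguishable size: in a full-panel run,
similar-sized monomers legitimately land in one group. The complex-bound
flag (apparent/monomer ≥ 2) marks at-least-dimeric apparent size.

## Synthetic-data generator

The generator defines the study conditions under which everything is
validated. Design: donors C1, C2 (healthy, 3 monthly time points), P1
(10 time points, episodes peaking at T1 and T8), P2 (5 time points, one
strong episode at T2); the `study` preset is their 21-sample union.

Concentrations follow c(p,t) = baseline · (1 + (fold − 1) · m(t)) with a
triangular episode multiplier of half-width 1 time point, so only the
peak sampling itself is perturbed — sampling is sparse relative to the
days-long inflammation kinetics. Baselines for the 22 anchors equal the
bundled reference values; hallmark baselines and peak values are the
study's reported ones (healthy CRP/SAA1/SAA2 ≈ 0.3/0.7/0.05 mg/dL; P2
peak 50/300/100 mg/dL with patient pre-episode baselines 1.0/1.5/0.5 so
the published fold changes and peak concentrations hold simultaneously).
Measurement noise is multiplicative log-normal with unit mean, default
CV 10% — consistent with the stability of control profiles; the
within-donor technical variance is a modeling choice, not a measured
value. LFQ values invert a configurable log-log calibration (identity by
default, non-trivial slopes for calibration-recovery tests). All
randomness flows through numpy's PCG64; same seed, same table, any
platform.

SEC runs place every species as a Gaussian in fraction space (σ = 1.5
fractions; no peak-shape information was available, and a Gaussian is the
standard idealization) centered at its assembled MW under the map, with
66 fractions spanning 3000→10 kDa. Each member protein's channel
integrates to its total concentration, so mass is conserved per protein.
Complexes: fibrinogen A2B2G2 (375 kDa), HP1-1 dimer (150), CRP pentamer
(120 = 5 × 24), calprotectin S100A8/A9 (24), IαI = ITIH1+ITIH2+bikunin
(225), TTR tetramer (55), A2M tetramer (720), SAA1 hexamer (70, healthy
state only), and an HDL particle that remodels: healthy composition
APOA1/A2/A4 at 200 kDa; at an episode peak the inflamed particle
(300 kDa) carries SAA1/SAA2 alongside reduced APOA. The displacement
fraction δ (default 0.5) sets the APOA negative response fold to 1 − δ.
The six kit standards and a Blue-Dextran-style void marker are emitted as
annotated calibrant channels with exact peak centers.

Not emulated: peptide-level effects, retention-time structure,
missingness beyond dropped fractions, between-donor baseline variation,
batch effects, and deconvolution of species sharing a protein. Passing
tests therefore demonstrate correctness of the estimators under the
stated generative model, not robustness to every artifact of real data.

## Problem sizes and determinism

Recovery statistics use 20–100 seeded replicates of the 21-sample (or
smaller) cohorts and single noise-free 66-fraction SEC runs — sizes at
which every check runs in seconds while the Monte-Carlo error of a mean
over 20 replicates (≈ 2–3%) stays well inside the 15% recovery
tolerances. The pipeline summary rounds floats to 8 decimals and sorts
keys so identical config + seed yields byte-identical JSON.

## Known limitations

* The peak-detection rule assumes hallmark episodes are large (≫ 5×);
  low-grade inflammation would need a different baseline model.
* With a single non-adjacent baseline time point (as in the 5-sample P2
  design), fold-change estimates inherit that one sample's noise.
* Apparent MW from a single centroid cannot represent genuinely multimodal
  elution; only the main peak is summarized.
* Coelution grouping is resolution-limited: unrelated species within
  ~1 fraction co-group, and group identity should be read together with
  the MW-compatibility tolerance.
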