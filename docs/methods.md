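# Methods

## Coordinates and data model

All intervals are 0-based half-open (BED convention) everywhere inside
the package; conversions happen only at I/O boundaries. A peak is an
interval with a single-base summit; every window is summit-centered.
"± h bp" windows are realized as `[s − h, s + h)`, i.e. 2h bases — the
inclusive 2h + 1 reading would shift each count by at most one base.
Stranded cut tracks are dense per-chromosome integer arrays (one per
strand), so window sums and binned profiles are exact integer slice
sums; bedGraph input is densified on read.

## Quantification and normalization

Each peak is quantified as the both-strand cut count in
`[summit − 200, summit + 200)`. Per-sample correction factors equalize
the median of the top-N counts: `f_s = g / m_s` with `g` the geometric
mean of the per-sample top-N medians. The geometric-mean reference
makes the factors symmetric in the samples, equal to 1 for identical
samples, and scale-equivariant (scaling a sample's counts by c scales
its factor by 1/c and leaves its normalized column unchanged up to the
common reference shift). N defaults to 25,000 at genome scale — about
the strongest 36% of a typical ~70,000-peak master set; on smaller peak
universes the same 36% fraction is used (`quantify.scaled_top_n`).
Keeping the median deep in the unchanged bulk of the distribution
matters: if N is small enough that the median rank lands near the
condition-dependent strong peaks, inducible peaks displace the ranks in
stimulated samples and bias their factors downward. Ties at the rank-N
boundary are resolved by count value only; the median depends only on
the multiset of retained values, so the result is platform-independent.

## Differential DHS classification

With pseudocount p (default 1.0, applied to normalized counts), a peak
is A-specific iff `(a_i + p)/(b_i + p) ≥ fc` (default 2) in both
replicate pairs, B-specific symmetrically, otherwise shared — so the
labels partition the union, swapping conditions swaps the labels, and
raising fc weakly shrinks both specific sets. Inducible DHSs are
specific peaks with `(stim + p)/(rest + p) ≥ 3`, where stim and rest
are replicate means of the peak's own arm. Union building merges
overlapping *or bookended* (gap 0) intervals, as the standard
sort|merge toolchain does; the representative summit of a merged peak
is the summit of the contributing peak with the highest normalized
count (ties to the smaller coordinate). Repeat exclusion drops peaks
overlapping a user-supplied repeat interval set by ≥ 1 bp; no
annotation download is attempted. Union membership uses a configurable
significance cutoff on normalized counts (a peak significant in at
least one sample enters the union); synthetic runs derive nothing from
it because planted peaks sit well above background.

### Count-rate cross-check

`count_rate_test` is a deliberately lightweight surrogate for a full
negative-binomial GLM: it z-tests the log ratio of factor-adjusted
replicate-mean counts, with variance `(1/μ_A + α)/n_A + (1/μ_B + α)/n_B`
where the overdispersion α is a method-of-moments estimate (median over
peaks of `(s² − m)/m²` of factor-adjusted replicates, clipped at 0),
followed by Benjamini–Hochberg correction. It reproduces the *role* of
an FDR-controlled second opinion on the fold-change calls — on the
default synthetic run essentially all fold-change-classified specific
peaks reach q < 0.05 — and makes no claim of numerical equivalence to
any published estimator. Identical inputs give p = 1 by construction.

## Gene expression groups

The expressed universe keeps genes whose per-condition replicate-mean
expression reaches 3 in at least one condition. Condition-specific
groups require `(hi + p)/(lo + p) ≥ 2` and `max(hi, lo) ≥ 50`; the
min-count is interpreted as "at least one of the two compared means",
and all boundaries are inclusive (≥). Inducible-specific groups
intersect the stimulated-comparison group with
`(stim + p)/(rest_own_arm + p) ≥ 2`. The high-variation set keeps genes
with any of the four condition ratios ≥ 10 in either direction. Fold
changes use replicate means with the pipeline-wide pseudocount; no
shrunken fold-change estimates are involved, and significance screens
can be layered on externally via a q-value column in the gene table.

## Proximity and overlap integration

Distances are unsigned summit-to-TSS base pairs; summits rather than
peak edges are used because they are single-base and deterministic.
Closest-gene assignment caps at 100 kb, with ties broken by smaller TSS
then lexicographic gene id. `fraction_within` is the share of group
genes whose nearest DHS lies within 50 kb, non-decreasing in the
distance by construction; `distance_bins` adds a "beyond/∞" bin so
fractions always sum to 1. Venn overlaps merge each set internally
first and count A-side: each merged A peak counts once if it overlaps
any merged B peak by ≥ min_overlap, so `a_only + both = |merged A|`.
The proximity null permutes gene-group membership over the expressed
universe (p = (1 + #{perm ≥ obs})/(n_perm + 1)); permuting labels
avoids needing a mappability or blacklist model for relocating DHSs.

## Footprint caller

Inside each DHS window every candidate of width w (grid 11–25 bp, step
2) with 35-bp flanks is scored by the one-sided binomial tail
`P(X ≤ x_obs)` with `X ~ Bin(n_tot, w/(w + 2·35))`, where `n_tot` is
the both-strand cut count of candidate + flanks. The per-candidate
score is `−log10 p` and is monotone decreasing in the candidate's cut
count. The reported candidate is the best-scoring one *among those with
footprint-like strand orientation* — strand-imbalance statistic
(plus-strand cuts in the upstream flank + minus-strand cuts in the
downstream flank) / (all flank cuts) at or above 0.6; without this
orientation constraint the minimum-p candidate frequently locks onto a
window *adjacent* to a real footprint, whose flank swallows both edge
pile-ups. Because the reported p is a minimum over the scanned grid, it
is Šidák-adjusted for the number of candidates before
Benjamini–Hochberg correction across DHSs; under positive correlation
of overlapping candidates this over-corrects, which is the conservative
direction for null calibration (a homogeneous Poisson track yields no
calls at α = 0.05). A DHS is called iff q ≤ α and the imbalance gate
passes; windows with fewer than 30 cuts in candidate + flanks are
flagged not evaluable and excluded from the correction. The caller is a
self-contained depletion statistic, not a reimplementation of any
published footprinter, and is named accordingly in outputs.

Motif scanning is IUPAC-consensus matching (both strands, overlapping
hits all reported) within ±100 bp of summits, against a small packaged
library of inducible-TF consensi (AP-1 `TGASTCA`, NFAT `TTTCC` core,
NF-κB `GGGRNNYYCC`, EGR `GCGKGGGCG`, MAF, LEF/TCF, IRF, and fixed-
spacing NFAT/AP-1 and AP-1/IRF composites). Position-weight-matrix
scoring and de novo discovery are out of scope.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not real genomes:

* **Counts.** Peak × sample counts are negative binomial with
  `Var = μ + α μ²`, α = 0.05 by default (a typical replicate-level
  dispersion for accessibility counts), around a shared mean of 50 cuts
  per window. Specific peaks are planted symmetrically (×√4 in their
  high arm, ÷√4 in the low arm) so the 4-fold effect leaves the average
  cuts per peak at the configured level. Inducible effects (×4)
  apply only in the stimulated condition of the peak's own arm —
  matching the analysis' definition of an iDHS and keeping the rank
  composition of the top-N normalization window balanced across
  conditions. Per-sample depth factors are log-normal (σ = 0.25 log2
  units), which the normalization stage must undo.
* **Genes.** 1,000 genes on a dedicated chromosome: 200
  stimulation-specific (4-fold up in T_Ag only), 100 resting-specific,
  10% unexpressed (mean 1), the rest flat at 30. Stimulation-specific
  genes receive a planted A-specific DHS within 50 kb of the TSS with
  probability 0.25 (background genes 0.05) — enrichment is planted by
  construction, so the true fraction is exact by design; the planted
  link peaks get their own count-matrix rows so the classifier can find
  them.
* **Footprints.** Profile DHSs carry ~300 uniform cuts per 400-bp
  window; planted footprints thin the central 15 bp by 60% and convert
  30% of the window's cuts into strand-offset edge cuts (plus-strand in
  the 10 bp upstream of the footprint, minus-strand downstream).
* **Repeats / ChIP.** Repeat intervals cover a subset of shared peaks
  plus intergenic background; a ChIP-like interval set covers 60% of
  A-specific peaks plus background intervals.

Everything derives from one `numpy` Generator seeded from
`SimulationParams.seed`, so identical seeds give byte-identical output
bundles. What the simulation does **not** emulate: sequence-composition
cut bias, mappability structure, realistic peak-width and inter-peak
spacing distributions, correlated replicate artifacts, and annotation
complexity (one TSS per gene). Passing recovery tests therefore
demonstrates the correctness and calibration of the statistical
machinery under its stated noise model, not performance on real
DNase-seq libraries.

## Problem sizes and determinism

The default synthetic study uses 20,000 peaks, 2 replicates × 4
conditions, 1,000 genes, 200 profile DHSs, 1,000 permutations, and
1,000 null DHSs for footprint calibration — sizes chosen so every stage
runs in seconds on one core while keeping Monte-Carlo error well inside
the tested margins. The end-to-end pipeline (`pipeline.run_all`) writes
plain-file stage outputs with a config-hash manifest; reruns with the
same seed are byte-identical (stage wall-times go to `run.log`, outside
the deterministic set), and a resume with a different config hash is
refused rather than silently mixing outputs.

## Known limitations

* The correction-factor formula fixes a convention (geometric-mean
  reference) where practice varies; any single designated reference
  sample would differ by a constant factor across all samples.
* The count-rate test's single pooled dispersion is coarser than
  per-peak shrinkage estimators; it is a plumbing cross-check, not a
  differential-accessibility method.
* The footprint caller ignores hexamer cut bias and uses a single
  global flank width; scores on real data would need bias correction.
* Distances are summit-to-TSS; peak-edge conventions would shift the
  50/100 kb fractions slightly.
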