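# chromaprime

Analysis pipeline for differential DNase-seq hypersensitivity in paired
T-cell states — naive (N) versus tolerized (T), resting (0) versus
antigen-stimulated (Ag) — together with a seeded synthetic-data
generator that plants every effect the analysis is meant to recover, so
each stage can be verified at desk scale.

## The problem

Repeated antigen exposure drives T cells into an anergic, tolerized
state. At the chromatin level this shows up as a redistribution of
DNase I hypersensitive sites (DHSs): some open-chromatin sites are
specific to the tolerized resting state (tDHSs, interpreted as
epigenetic priming of immune-repressive genes), others form only upon
stimulation (inducible DHSs, iDHSs), and primed loci sit close to the
genes whose induction they enable. The pipeline quantifies, normalizes,
classifies, and integrates these signals:

1. **Quantify** — count 5′ DNase I cuts (both strands) in the half-open
   window `[s − 200, s + 200)` around each peak summit `s`.
2. **Normalize** — per-sample correction factor
   `f_s = g / m_s`, where `m_s` is the median count of the top-N peaks
   of sample *s* (N = 25,000 at genome scale, the strongest ~36% of the
   master peak set) and `g` is the geometric mean of the `m_s`. After
   scaling, every sample's top-N median equals `g`.
3. **Classify** — with pseudocount `p = 1`, a peak is condition-A
   specific iff `(a_i + p)/(b_i + p) ≥ 2` in *both* replicate pairs
   `i = 1, 2`; an iDHS additionally satisfies
   `(stim + p)/(rest + p) ≥ 3` in its own arm. An overdispersed
   count-rate z-test with Benjamini–Hochberg correction cross-checks the
   fold-change calls.
4. **Gene groups** — expressed universe (mean ≥ 3 in ≥ 1 condition),
   condition-specific groups (2-fold, min count 50), inducible-specific
   groups (additionally 2-fold over the own-arm resting state), and a
   10-fold high-variation set.
5. **Integrate** — summit-to-TSS distances, closest-gene assignment
   within 100 kb, fraction of group genes within 50 kb of a DHS set,
   distance-bin histograms, A-side Venn overlaps with ChIP peak sets,
   and a gene-label permutation null for proximity enrichment.
6. **Profiles & footprints** — 10-bp-binned tag-density matrices over
   ±1 kb, IUPAC consensus motif scanning ±100 bp of summits, and a
   footprint caller scoring the one-sided binomial tail
   `P(X ≤ x_obs)`, `X ~ Bin(n_tot, w/(w + 2f))` for a width-`w`
   candidate inside its flanks, gated on a strand-imbalance statistic
   (forward cuts piling upstream, reverse cuts downstream) and
   BH-corrected across DHSs.

The synthetic generator (`chromaprime.simulate`) plants all of this
with known truth: negative-binomially dispersed counts
(`Var = μ + 0.05 μ²`) over 20,000 peaks with 5% tolerized-specific and
5% naive-specific sites at 4-fold, arm-matched inducible effects,
expression groups whose genes carry a 25% within-50-kb DHS link rate
against a 5% background, and footprints carved as 60% central cut
depletions with strand-offset edge cuts.

## Worked example

```
python analysis/01_simulate.py          # seeded bundle -> results/run/
python analysis/02_quantify_normalize.py
python analysis/03_classify_dhs.py
python analysis/04_expression_groups.py
python analysis/05_integrate_proximity.py
python analysis/06_profiles_footprints.py
```

With the default seed 7 this prints, among other lines:

```
tDHS: 1012 called, sensitivity 0.916, FDP 0.015
nDHS: 947; T_Ag iDHS: 531; N_Ag iDHS: 436
fold-change vs rate-test concordance on specific DHSs: 100.0%
25.0% of 196 TAg-specific genes lie within 50 kb of a tDHS (universe null 9.0%, permutation p = 0.000999)
footprints: 108 called of 200 DHSs; sensitivity 0.973, FDP 0.000
```

Reading: of 1,089 planted tolerized-specific DHSs the 2-fold replicate
rule recovers 91.6% with 1.5% false discoveries; the planted 25%
proximity enrichment of stimulation-specific genes is recovered exactly
and is highly non-random; and the footprint caller finds 97% of planted
protected sites with no false calls. The same stages can be run in one
go with `chromaprime.pipeline.run_all`, which also writes a
`report.json` tallying every stage.

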