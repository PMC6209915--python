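# Methods

## Pipeline overview

`pathcombo` turns a genes × samples intensity matrix with designated
drug-free controls into ranked combination-partner suggestions, and
scores the wet-lab experiments that test them. The stages are:

1. **Normalization.** Quantile normalization across samples on the
   linear intensity scale: every sample's sorted vector is replaced by
   the across-sample mean of sorted vectors, preserving within-sample
   ranks. Ties within a sample receive the mean of the reference values
   at the tied ranks. Logging happens only later, inside the pathway
   score, so the pipeline operates on linear intensities throughout.
2. **Case-to-normal ratio (CNR).** For each case sample and gene,
   `max(case, floor) / max(geomean(controls), floor)`, where the
   geometric mean pools every control sample of the same cell line
   across all control timepoints. Controls are pooled rather than
   timepoint-paired because the control cultures are biological
   replicates of one drug-free condition; pairing would add variance
   without removing bias.
3. **Pathway activation strength (PAS).**
   `PAS_p = Σ_n ARR_np · log10(CNR_n)` over the pathway's member genes
   measured on the array. A member absent from the data contributes 0
   (equivalent to CNR = 1) — the only convention under which a sample
   identical to its controls scores exactly 0 for every pathway — and
   per-pathway coverage (fraction of members measured) is reported so
   poorly covered pathways can be inspected. PAS is not divided by
   pathway size, because the score is a sum of signed per-gene
   log-effects; a size-normalized variant exists behind
   `size_normalize=True` for sensitivity analysis only.
4. **Target prediction.** Per condition, the ⌈fraction·P⌉ pathways with
   the highest signed PAS are selected (default fraction 0.10; ceiling
   so small databases still select one pathway; boundary ties broken by
   pathway name for determinism). Genes are ranked by the number of
   selected pathways containing them — membership counts regardless of
   ARR weight, including weight 0 — and the maximal-count stratum is the
   candidate-target set. Selection uses signed PAS (upregulated
   pathways); `use_abs=True` switches to |PAS| for sensitivity analysis.
   An optional alias table maps gene symbols to family-level labels
   (e.g. PLCG1 → PLC) at report/matching time only; the computation
   itself stays at gene-symbol level.
5. **Combination suggestion.** Every drug in the drug→target map whose
   target set covers one of the top-n ranked genes (directly or via
   alias) is suggested, excluding the condition's own baseline drug;
   suggestions are ordered by best occurrence count, then drug name.

## Dose–response and synergy analytics

Viability is computed from MTT optical densities as
`(OD_treated − mean OD_blank) / (mean OD_control − mean OD_blank)`, kept
as a fraction. IC estimation fits a four-parameter logistic
`v(c) = bottom + (top − bottom)/(1 + (c/IC50)^hill)` to the
replicate-mean curve by bounded least squares (initial values: top = max
viability, bottom = min viability, IC50 = grid median, hill = 1; bounds
bottom ≥ 0, hill ∈ [0.1, 10], top ≤ 1.5) and inverts it at viability
1 − level. If the fit fails or cannot reach the target, the estimator
falls back to monotone log-linear interpolation between the bracketing
doses, flagged as such. A curve that never drops below the target within
the grid returns a right-censored estimate rendered as "≥ max-dose".

The combination design titrates one drug with the partner fixed at its
IC20. Because the reported combination curve is renormalized by the
partner-alone viability, the Bliss computation first multiplies it back
by (1 − Y2) to recover absolute viability — Bliss independence is
defined on absolute effects. Inhibitions (1 − viability) are clamped to
[0, 1]; no further baseline rescaling is applied. Per nonzero dose the
excess over `Y1 + Y2 − Y1·Y2` is recorded, and the score is 100 × the
mean excess. Classification uses strict inequalities: score > 5
synergistic, < −5 antagonistic, otherwise additive — the boundary values
themselves are additive. The predicted-vs-random group comparison is a
two-sided Welch t-test (unequal variances, Welch–Satterthwaite df).

## Synthetic-data generator

The generator emulates the study design end to end with known ground
truth. Defaults (the study conditions; chosen once):

| parameter | default | rationale |
|---|---|---|
| genes / pathways | 400 / 60 | preserves the ~6:1 gene:pathway ratio of a 378-pathway knowledge base at a size where hundreds of seeded runs complete quickly |
| pathway size | 5–20 members | typical curated-signaling-set sizes |
| planted pathways | 6 | equals the top decile of 60, so full recovery is exactly the selected set |
| planted effect | +0.5 log10 per member | ~3-fold regulation, a strong but realistic microarray effect |
| hub gene | member of all planted pathways, ARR +1 | the quantity the pipeline must recover |
| baseline | lognormal, log10 sd 0.25 around mean 2.0 | microarray-like intensity spread |
| noise | gaussian log10 sd 0.2 | replicate-level biological + technical noise |
| controls | 5 replicates (weeks 0–16) | matches the pooled-control design |
| dose grid | 0, 0.8, 1.56, 3.1, 6.25, 12.5, 25, 50 µM, quadruplicate | the standard plate layout |
| viability noise | multiplicative, CV 5% | typical MTT well-to-well scatter |

Planted expression effects are ARR-signed (activators up, repressors
down by the same log10 magnitude), so planted pathways are genuinely
upregulated whatever their ARR composition; a gene in several planted
pathways accumulates their shifts. Combination plates are synthesized
under the Bliss null `survival = (1 − Y1)(1 − Y2)` plus a configurable
injected per-dose inhibition excess, then divided by the partner-alone
viability before being written — the same renormalized form a lab
reports — so the analysis code is forced to implement the inversion
correctly. Inhibition is capped at 1 when injecting excess, so at doses
where the null effect is already near-complete the realized excess is
smaller than the injected value; with a mid-grid IC50 this depresses the
recovered score by a few percent of its value, which is physical rather
than an artifact.

All randomness flows from a single integer seed through
`numpy.random.default_rng`, with per-generator sub-streams derived from
stable CRC32 labels, so outputs are platform-independent and independent
of call order.

**What the generator does not emulate:** probe-level artifacts, batch
effects, culture drift, correlated gene–gene noise, plate-position
effects, or partner-dose measurement error (the partner inhibition is
supplied exactly). Tests passing on synthetic data therefore demonstrate
the correctness and calibration of the computations, not the biological
validity of predictions on real arrays.

## Numerical choices

- Intensity floor 1.0 (raw scale) on both CNR numerator and denominator
  prevents infinite log-ratios from zero intensities.
- Duplicate gene rows (multiple probes per symbol) collapse by
  per-sample maximum; gene symbols are uppercased and stripped at read.
- Quantile normalization of a single-gene matrix is a logged no-op.
- Selection and ranking ties break lexicographically, making every
  report byte-reproducible for identical inputs.
- The 4PL fit runs with tightened least-squares tolerances (1e−14) so a
  noiseless synthetic curve is inverted to machine-level accuracy.
- GMT pathway input (no ARR column) defaults every weight to +1 with a
  logged warning; the 3-column TSV dialect is the lossless format.

## Problem sizes

The bundled test-suite and acceptance computations use 100 seeded
end-to-end runs for hub recovery, 200 random small instances for the
PAS oracle comparison, 100 seeds each for Bliss-null/injected-excess
calibration and IC50 recovery, and 200 reruns for the Welch power
scenario — sizes at which every quantity is stable to well within its
acceptance margin while the whole suite runs in seconds.

## Known limitations

- Pathway topology is reduced to membership + ARR weight; no network
  propagation.
- Target identity is gene-symbol based; family-level aggregation is a
  report-time relabeling, not a many-to-one collapse of counts.
- Only the Bliss model is implemented (the design is 1-D titration with
  a fixed partner dose); Loewe/ZIP/HSA are out of scope.
- PAS carries no significance estimate; dispersion summaries
  (per-condition sd across pathways) are descriptive.
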