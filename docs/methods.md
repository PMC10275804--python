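# Methods

## Evolution model

Populations are vectors of frequencies over copy-number classes
(default: zero-copy, one-copy ancestral, three-copy amplified). Each
discrete generation applies, in order:

1. **Mutation.** The one-copy class loses probability mass
   `delta_amp` to the amplified class(es) (split equally when several)
   and `delta_del` to the zero-copy class. Defaults: `delta_amp = 1e-4`,
   `delta_del = 1e-5` per cell per generation — the order of magnitude
   of locus-specific amplification rates inferred in reporter-based
   chemostat selections, with deletions rarer.
2. **Selection.** Class i is reweighted by relative fitness `1 + s_i`
   (ancestral s fixed at 0; default amplified s = 0.1) and the vector is
   renormalized.
3. **Drift** (`mode="wright_fisher"` only). Class counts are resampled
   multinomially at effective population size `pop_size` (default 1e5).

This is the simplest recurrence whose deterministic two-class limit is
exactly logistic in the log-odds: with pure selection, logit p increases
by ln(1+s) per generation, which is the identity the S_up estimator
relies on (and which the tests verify to 1e-10).

The model deliberately has a single amplified class by default — no
clonal interference between distinct CNV alleles — because the gated
readout ("two or more copies") cannot distinguish them anyway.

## Observation model

Per sampled generation, one experimental sample and three control
samples (pure zero-, one- and two-copy populations) are rendered,
mirroring control strains propagated in parallel and measured alongside
each timepoint. Controls are simulated as non-evolving: real control
populations do adapt at other loci, but their reporter signal stays
stable, and only that stable signal matters downstream.

For a singlet cell of class with copy number c:

* size `S ~ lognormal(size_mu, sigma)` with CV 25% (typical yeast
  forward-scatter spread), median ~5e4 instrument units;
* `FSC-A = FSC-H = S` (singlets sit exactly on the diagonal);
  `SSC-A = S·exp(N(0, 0.25))` — the SSC spread is an internal constant,
  since nothing downstream is sensitive to it;
* fluorescence `F = fluor_per_copy · (c/ploidy)^β · S · exp(N(0, σ_f)) +
  autofluorescence`, with fluorescence CV 15% by default, lognormal
  autofluorescence (median 200), and β (`copy_scaling_exponent`)
  defaulting to 1. β < 1 reproduces the empirically observed sub-linear
  scaling of multi-copy fluorescence; it is a parameter rather than a
  hard-coded behaviour.

Doublets (default 5%) sum two cells' areas and fluorescence but keep the
larger height — placing them below the FSC-A≈FSC-H diagonal, which is
precisely the signal the singlet gate uses. Debris (default 5%) is drawn
~100× smaller than cells with autofluorescence only. Zero-copy cells
carry autofluorescence only.

What the simulator does **not** emulate: instrument drift and day-to-day
sensitivity changes, spectral spillover/compensation, saturation and
binned (integer) intensities, dead cells and size–fluorescence
correlations beyond strict proportionality, cell-cycle structure, and
adaptation occurring inside control populations. Tests passing on these
synthetic data therefore validate the analysis logic under a clean,
known generative model — not robustness to every instrument artifact;
the per-timepoint recalibration mode and the template-file escape hatch
are the tools for real-world drift.

Seeds: the master seed spawns a documented child sequence
(`SeedSequence((seed, counter))`, counter 0 for the evolution run, then
`1 + 4·timepoint + role`), so any individual sample file can be
regenerated independently.

## Transforms

Scatter channels use log10 with a floor of 1 instrument unit (log
defined at zero). Fluorescence uses the standard logicle/biexponential
scale; the forward transform inverts the biexponential numerically
(vectorized bisection + Newton polish, agreeing with an independent
root-finder to <1e-6). Defaults T = 2^18, M = 4.5, W = 0.5, A = 0 are
conventional display values — the parameterization is exposed because
instruments and analysts vary here.

## Gating

The hierarchy is Cells → Singlets → Copy0/Copy1/Copy2plus, with every
boundary lower-inclusive/upper-exclusive, so the three copy gates
partition their axis and cannot double-count.

* **Cells**: rectangle in log FSC-A × log SSC-A whose lower FSC-A edge
  is the `q_debris` (default 0.05) quantile of pooled control FSC-A;
  other edges are data extremes ± 0.5 decades. With debris ~2 decades
  below cells, any quantile inside the gap separates them cleanly.
* **Singlets**: band |log FSC-H − log FSC-A| ≤ w, with w = 4·MAD of the
  control residual, floored at 0.02 decades (the floor matters because
  ideal singlets have zero residual, and a measure-zero band would be
  fragile against any future jitter).
* **Copy gates**: events are scored on the size-detrended coordinate
  `u = logicle(F) − a·(log10 FSC-A − x_ref)`, where the shear `a` is the
  OLS slope of transformed fluorescence on transformed FSC-A in the
  one-copy control (≈1 under proportional scaling; clipped to [0, 1.5];
  `shear=0` recovers plain horizontal boundaries). Boundaries are
  quantile midpoints: the 0|1 cut halfway between the 99.5th percentile
  of the zero-copy control and the 0.5th percentile of the one-copy
  control on u, and likewise for 1|2+. Copy0 is unbounded below,
  Copy2plus unbounded above. Calibration requires strictly ordered
  control medians, else it aborts with a calibration error.

The sheared construction is the package's stand-in for manual gate
drawing: hand-drawn gates on FSC-A × fluorescence plots follow the size
diagonal, and a purely horizontal cut would fold the full cell-size
spread (~0.11 decades at 25% CV) into the copy-number axis, roughly
decupling the one-↔two-copy misclassification rate. Detrending by size
leaves only fluorescence noise (~0.065 decades at 15% CV) across the
0.30-decade one-to-two-copy separation. Percentile edges (rather than
min/max) keep boundaries robust to outliers; both the quantiles and the
shear are configurable, and a serialized template (JSON) can be edited
or supplied wholesale to reproduce a manual workflow.

Assessment follows the 85% containment rule: for each control strain,
the fraction of its singlet events pooled across all timepoints that
fall inside its own copy gate must exceed 0.85; per-timepoint fractions
are reported alongside for diagnosis. Default calibration uses
timepoint-0 controls for the whole course, with per-timepoint
recalibration available (`calibrate_per_timepoint`) for drifting
instruments. In the CLI a containment failure warns by default and is
fatal under `--strict`, since in practice it triggers a gate redraw
rather than invalidating the data.

## Quantification

Concentration is `F / FSC-A` on the raw linear scale (the logicle scale
is for display geometry only; ratios are meaningful only in linear
units). Events with FSC-A ≤ 0 are excluded and counted. The continuous
copy-number estimate is `ploidy × concentration / median(one-copy
control concentration)`; it is not rounded. Per-sample summaries report
gate proportions and the median concentration over singlet events
(numpy's midpoint convention for even counts); the median convolves CNV
frequency with per-cell copy number and is reported as a descriptive
summary, not an estimator. Samples with <1000 singlets are flagged
`low_count` rather than rejected.

Trajectories are ordered by generation; missing timepoints stay gaps
(never interpolated); the one-copy control's proportion inside the
variant gate is attached per timepoint as the empirical false-positive
series. A `variant_class="copy0"` switch makes deletion selections
first-class (the zero-copy gate becomes the variant of interest).

## Dynamics

* **T_up, consecutive rule (default)**: first timepoint of the earliest
  run of k = 3 consecutive *sampled timepoints* with p > θ = 0.05.
  "Consecutive generations" is read as consecutive samples because
  samples are ~10 generations apart and literal generations are
  unobserved.
* **T_up, FPR rule**: threshold = mean + 1 SD (sample SD across
  timepoints) of the one-copy control's variant-gate proportion series;
  T_up is the first timepoint above it.
* **S_up**: OLS slope of ln(p/(1−p)) on generation over the rise
  window. Timepoints with p ∈ {0, 1} are excluded and counted; a
  pseudo-count option (clip at 1/(2·n_singlets)) exists for sparse data
  and is recorded in the fit.
* **Rise window**: T_up to the first timepoint with p ≥ 0.9·max(p),
  falling back to the last timepoint when the rise never plateaus. The
  extent of the "initial expansion" is not canonically defined; this
  rule is a documented convention, always overridable with an explicit
  window, and the choice used is recorded in the output.
* **S_down / T_down**: the mirrored slope after the trajectory maximum
  and the first post-maximum timepoint below θ; both None when the
  trajectory never declines (the common outcome in amplification
  selections).

S_up is reported as the log-odds slope per generation together with
`100·(e^slope − 1)`, the percent-per-generation form; under the
evolution model the slope equals ln(1+s) exactly, which anchors the
parameter-recovery tests (median relative error ≈2% over 20
Wright–Fisher replicates at s = 0.12 with 10,000 events/sample).

## Numerical and design notes

* Logicle forward inversion: 30 bisection iterations + 4 Newton steps,
  accurate to ~1e-12 decades; inputs must be finite.
* All boundary comparisons are `>=` on the lower edge, `<` on the
  upper; the singlet band is closed (|d| ≤ w) so the degenerate w = 0
  band means exact FSC-H = FSC-A equality.
* Sorting uses generation as the only key; duplicate
  (population, generation) pairs are an error, not a merge.
* Problem sizes in the test suite (event counts of 2,000–10,000,
  20-replicate recovery studies, 150–250-generation courses) match the
  design scale of the experiments the package targets while keeping the
  default suite fast.
* Known limitations: no spectral unmixing or compensation; no absolute
  calibration (MESF beads); no correction for residual one-/two-copy
  overlap beyond gating; copy-number resolution degrades above ~3
  copies as fluorescence distributions overlap; the frequency estimate
  is biased by the gating false-positive rate at very low p (the FPR
  series is supplied so users can see that floor).
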