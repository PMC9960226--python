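# Methods

## The coupled-editing model

A reporter-coupled library places a copy of each guide's target site (the
"reporter") on the same lentiviral cassette as the guide, so the guide
cuts both its endogenous target and its own reporter. The analysis rests
on two facts about such screens.

First, editing of the reporter and of the endogenous target are coupled
within a cell: both depend on the same Cas9/sgRNA dose. A cell with an
edited reporter almost certainly has an edited target. Consequently, when
target disruption kills cells, those cells take their edited reporters
with them, and the observed indel fraction among surviving reads
*underestimates* the true edited fraction — by exactly the amount of
dropout.

Second, the terminal state of a guide's population is fully described by
two parameters: the true edited-cell fraction `X` (the guide's activity)
and the relative viability `v` of edited cells. With unedited cells at
viability 1,

    FC        = (1 − X) + X·v  = (v − 1)·X + 1
    indel_obs = X·v / FC

The pair `(FC, indel_obs)` therefore determines `(X, v)` exactly:

    X = 1 − FC + FC·indel_obs
    v = (FC − (1 − X)) / (FC_v=1(X) − (1 − X))

This inversion is an algebraic identity, not an approximation; the test
suite checks it to 1e−9 on a grid of `(X, v)` and end-to-end on
noiseless simulated screens.

### Control regressions

Two nuisance effects must be calibrated before the inversion, and both
come from negative-control guides (guides whose target disruption is
phenotypically neutral):

1. **FC₀ (regression 1: raw FC on observed indel).** Even controls drift:
   the screen-wide dropout of essential genes inflates every surviving
   guide's frequency (mean-fitness renormalisation), and cutting itself
   costs fitness. Ordinary least squares of raw FC on observed indel over
   controls extrapolates to the fold change of a hypothetical
   zero-activity control, FC₀ = the intercept. All fold changes are
   normalised: `FC_norm = FC_raw / FC₀`. In the generative model used
   here, FC₀ equals 1 / (mean population fitness) exactly when the
   DNA-damage cost is zero, which is why noiseless recovery is exact.

2. **FC_v=1(X) (regression 2: FC_norm on X).** Cas9 cutting triggers a
   DNA-damage response with a mild proliferation cost, so even a neutral
   knockout with high activity drops out slightly. OLS of `FC_norm` on
   `X` over controls gives the fold change expected of a *neutral* gene
   as a function of activity. Its slope estimates the DNA-damage cost per
   unit editing: in the generative model the control relation
   `FC_norm = s·X + const` is exactly linear, so the slope recovers `s`
   without bias (the sampled-recovery test demands ±0.02 at 500
   controls). `v` then interpolates between the floor `FC_v=0 = 1 − X`
   (all edited cells die) and the ceiling `FC_v=1(X)`.

Regression 1 is deliberately fit on the *observed* indel, and regression
2 on the corrected `X`, mirroring the order in which the quantities
become available. For libraries without designated controls, guides
targeting user-declared neutral genes can serve as the control set.

### Reliability at low X

As `X → 0` the floor and ceiling converge and the `v` denominator
vanishes: small FC noise becomes a large `v` fluctuation. Guides are
therefore *flagged*, not dropped: `reliable = (X ≥ x_min)` with
`x_min = 0.05` by default, plus a separate `high_confidence_x` annotation
at `X ≥ 0.44` for stricter diagnostic filtering. Denominators below
1e−6 on the FC scale yield an undefined (NaN) `v` with a cleared
`v_defined` flag rather than an exception. `v` itself is never clipped —
values above 1 are meaningful in enrichment screens — while `X` is
reported both raw and clipped to [0, 1] with a clipping flag.

## Read classification

Read 2 carries the sgRNA cassette: the spacer is extracted after a fixed
anchor (the 3′ end of the U6 scaffold, configurable), located exactly or
within 1 substitution. The 20-mer is matched to the library exactly,
then within a Hamming radius of 1; equidistant ties are left unassigned
rather than guessed.

Read 1 carries the reporter. The guide-specific segment (protospacer +
PAM) sits between fixed flanks; 12-nt flank probes are located with ≤ 2
mismatches each, and the between-flank region is then:

1. **Coupling check** — edit-distance compared (edlib, unit costs)
   against the expected segment and every other guide's segment; a
   strictly closer foreign segment marks the read a chimera
   (template switching / PCR crossover). Uncoupled reads stay in
   `n_total` but are excluded from both the indel numerator and
   denominator.
2. **Indel call** — global alignment to the expected segment with affine
   gap scores (match +1, mismatch −1, gap open −6, extend −0.25), so one
   indel is always preferred over a run of substitutions. A read is
   *edited* only if some insertion or deletion footprint intersects the
   window `cut_offset ± 10` nt; substitution-only reads are unedited, so
   sequencing error does not inflate indel frequencies. No base-quality
   filter is applied by default (an optional mean-Q threshold exists).

The 10-nt window reflects the physics of the assay: the reporter cannot
report large resections, so the detectable footprint is local to the cut.

## Quantification and QC

Frequencies are computed over library-assigned reads with a pseudocount
of 0.5 added per guide in both samples — this keeps fold changes finite
for full dropouts of essential genes while perturbing well-covered guides
negligibly. The QC statistic is reads-per-thousand in the reference
sample; guides below 0.1 rpt are flagged (they show replicate-to-replicate
drift) and excluded from all fits and scores but carried in outputs.
Replicates are quantified independently, then FC and indel are averaged
at the metric level; replicate concordance is reported as Pearson r
(two-tailed) on log₂FC and on indel. Diagnostic smoothing uses the
moving median over the 20 nearest x-neighbours (exact sliding-window
implementation, verified against an all-pairs oracle).

## Benchmarking

Gene scores aggregate guide values (median by default; mean and
second-best are available). Lower score = more depleted; essential genes
are the positives. ROC-AUC is the tie-corrected Mann–Whitney pair
probability. dAUC uses rank-prefix recovery curves: rank *all* entities
ascending, plot the fraction of each label set recovered in the top
`t·N` ranks, and subtract the non-essential area from the essential
area — this rewards rankings that both pull essentials up and push
non-essentials down. Recall-at-FDR and FDR-at-recall come from an
exhaustive threshold sweep. Ranking ties break by entity id for
determinism; the tie-corrected AUC is invariant to that choice. Exported
pseudo-counts are `round_half_up(max(0, initial_count × metric))` in
MAGeCK layout, usable by MAGeCK and DrugZ.

## The simulator

`screen_sim` generates the study conditions the rest of the package is
tested under. Defaults: 500 genes × 3 guides (100 essential at
`v ~ U(0.1, 0.3)`, the rest neutral at `v = 1`), 100 negative controls,
activity `X ~ U(0.05, 0.95)`, coupling fidelity κ = 0.94, DNA-damage
slope s = −0.1, lognormal initial abundances (σ = 0.5), and 2×10⁶ reads
per sample. κ and s sit where aggregate measurements of such libraries
put them: roughly 94% of reporters correctly paired, and a ~10% fitness
cost of cutting.

Growth is modelled as a single terminal multiplier per guide
(`fc_expected` in closed form), not per-day dynamics; intermediate
timepoints are emulated by linearly scaling `X` (a stand-in, not a
kinetic model). Read sampling is multinomial over guides at fixed depth;
coupled reads are a binomial thinning at κ (emulating a classifier that
recognises and excludes swapped reporters), and edited reads a binomial
draw among coupled reads. FASTQ rendering writes the spacer cassette on
read 2 and the reporter on read 1, with 1–3 nt deletions at the cut for
edited reads (insertions behind a config fraction), a protospacer swapped
from a random other guide for decoupled reads (edit state drawn from the
population average, independent of the cell), and iid substitution
errors. All randomness flows from the config seed through fixed,
stage-separated streams; identical seeds give bit-identical outputs.

What the simulator does **not** emulate: realistic indel spectra (large
deletions, in-frame bias), chromatin effects on cutting, PCR duplicates
and instrument error profiles, copy-number artefacts, off-target
cutting, and per-day editing kinetics. Passing tests therefore show the
*inference machinery* is correct under the coupled model, not that real
screens satisfy the model.

## Problem sizes in tests and the acceptance script

Routine tests use screens of 10–100 genes at 5×10³–5×10⁵ reads; the
acceptance checks use ~1000 guides (501 targeting + 500 controls) at
2×10⁶ reads for parameter recovery, ten 1600-guide screens for the v-vs-FC
benchmark, and 10⁴ rendered read pairs for classifier fidelity. These
sizes keep every property measurable with comfortable statistical margin
while the whole suite runs in well under a minute of simulation time.

The v-vs-FC benchmark comparison is made on guide-level rankings labelled
by gene essentiality. At gene level (median of three guides, X ≥ 0.2,
depth 2×10⁶) both methods separate the classes perfectly and the
comparison carries no information; guide-level ranking is where
low-activity guides actually misrank fold change, and it matches the
tiling-screen ROC construction in which individual guides are labelled by
their target gene.

## Known limitations

- The control regressions are ordinary least squares; a handful of
  outlier controls can tilt FC₀. Robust variants were deliberately left
  out to keep the estimator transparent.
- `X` estimates inherit binomial noise from the coupled-read count; at
  low coverage the clipped `X` can sit at 0 or 1, where `v` is undefined
  or saturated.
- The coupling check compares against every library segment per read
  (O(library) per read); for very large libraries a k-mer prefilter
  would be the next step.
- The shipped essential/non-essential gene lists are small curated
  subsets intended for tests and examples; real benchmarking should use
  the full published core sets.
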