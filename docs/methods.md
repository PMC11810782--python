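# Methods

This note documents the models, defaults and numerical choices behind
`mapscreen`, and what the synthetic-data generator does and does not emulate.

## Bulk solubilization from dithionite quenching

Membrane-active polymers (MAPs) excise patches of a fluorescently labeled
membrane into open nanodiscs; unsolubilized material remains as sealed
vesicles. Dithionite reduces fluorescent lipid headgroups on every surface it
can reach — both leaflets of an open disc, but only the outer leaflet of a
sealed vesicle. With a reading fl1 taken after solubilization and fl2 after
quenching, the residual fluorescence 2·fl2 reconstructs the total vesicular
signal, and

    bulk solubilization [%] = 100 − (2 · fl2 / fl1) · 100.

The value is clamped to [0, 100] with a flag rather than raised as an error:
under reading noise (fl2 slightly above fl1/2) or incomplete labeling the raw
value legitimately exits the physical range, and a plate-scale screen should
complete and report rather than abort. Replicates aggregate as mean ± sample
(n−1) standard deviation; a single replicate reports sd 0 by default.
Blank-well background subtraction is not applied by default.

The GFP readout (`gfp_extraction_efficiency`) is the simpler ratio
100 · fl_post / fl_pre between pre-solubilization and cleared
post-solubilization readings of a GFP-tagged target, clamped the same way.
The denominator is the pre-spin reading of the solubilized membrane; no
attempt is made to model losses before solubilization.

### Quench simulator noise model

`synth.simulate_quench` decomposes measurement noise at CV c into:

* a per-well scale factor ~ lognormal(mean 1, CV c) multiplying **both**
  readings — pipetting, labeling and sample-amount variability. The ratio
  assay is designed to cancel exactly this term, and it does;
* a quench-step factor ~ lognormal(mean 1, CV c) on fl2 alone — variability
  of dithionite penetration and incomplete quenching, the component that
  actually propagates into the readout.

This choice makes the simulator honest about why the assay is ratiometric:
with only shared noise the readout would be exact, and with fully independent
per-reading noise the error would be inflated by a factor ~√2 relative to
what a paired same-well measurement exhibits. At c = 0.05 the resulting mean
absolute error of the readout over a [0, 1] grid of disc fractions is ≈ 1.9
percentage points (clamping at the range edges slightly shrinks it).

## The LFQ screen and its simulator

The simulated screen follows the study design: 13 extraction conditions
(11 polymers across the SMA, ChloroSMA and AASTY chemistry classes, plus the
RIPA and NP40 detergent controls), 2 biological × 4 technical replicates.
Measured intensity for protein i in condition c is

    y = base_i · eff_ic · B_icb · T_icbt,        y := 0 if y < threshold,

with B a lognormal factor (mean 1, CV `cv_biological`, default 0.2) shared
by all technical replicates of a biological preparation, and T an independent
lognormal factor per measurement (CV `cv_technical`, default 0.1). The
nested structure means biological-replicate R² is governed by
`cv_biological` independently of technical noise. The CVs of the real screen
are not published; the defaults are conventional placeholders and are
explicit `NoiseModel` parameters, not constants.

Missingness is left-censoring at a detection threshold
(missing-not-at-random), the simplest mechanism that reproduces
low-abundance dropout and exercises the biological-replicate detection
filter. `detection_threshold_for_censoring` picks the threshold as a
quantile of the *noise-free* intensity surface, so a run can state "5%
censoring" without reference to any noisy realization.

Ground-truth effect sizes: each protein gets one preferred condition with
efficiency ~ U(0.4, 0.95); every other condition extracts an independent
U(0.1, 0.7) fraction of that — the several-fold spread between conditions
seen in real per-protein profiles. Base abundance is 10^N(6.5, 0.9) (about
three decades, as in LFQ data), molecular weight lognormal around 55 kDa,
and transmembrane-helix counts uniform on 1–14 for integral proteins.
Decoy and contaminant rows are generated and flagged so the corresponding
filter always has work to do.

What the generator does **not** emulate: peptide-level quantification and
protein-group ambiguity, correlated (class-wise) extraction preferences,
batch effects between acquisitions, intensity-dependent CVs, and
match-between-runs artifacts. Passing tests therefore demonstrate that the
pipeline's arithmetic and filtering logic are correct and recover a known
truth under realistic noise — not that any particular biological conclusion
transfers to real data.

## Filtering rules

* Decoy (`Reverse == '+'`) and contaminant rows are removed first.
* A protein is retained **per condition** only if detected (LFQ > 0 in at
  least `min_tech_detected` technical replicates, default 1) in *every*
  biological replicate of that condition; a row survives globally if
  retained in ≥ 1 condition. Both the per-condition mask and the global
  survival decision are logged. The alternative reading of the rule
  (detection anywhere in the screen) is recoverable from the logs.
* Membrane annotation matches by accession first, then unique gene name;
  ambiguous or unmatched rows go to a machine-readable review list instead
  of being silently dropped. Manual curation is externalized as an
  include/exclude override file, because in-code curation is irreproducible.

## Database construction

Replicate averaging is the arithmetic mean of retained, positive intensities
on the linear LFQ scale. Zeros inside a retained condition are excluded from
the mean — a zero encodes censoring, not an abundance — and the count of
such exclusions is logged. Per protein, the condition with the highest mean
is scaled to exactly 100% (the division is ordered so the self-ratio is
exactly 1.0 in floating point) and all other conditions are relative to it.
Exact ties are broken lexicographically and flagged. "Not detected" is NaN
end to end, distinct from 0%. Optional median-centering of sample columns
exists behind a flag but is off by default, since plain averaging is the
declared behavior.

The database serializes as a long-format TSV (floats written in shortest
round-trip `repr` form and parsed with correctly rounded `float()`, so
save→load is bit-exact) plus a JSON sidecar carrying the version, condition
classes, annotation metadata and build provenance.

## Secondary metrics

* **Solubilization index** of a protein set in a condition is the plain mean
  (Σ xᵢ)/n of the members' scaled values — bounded by the member extremes and
  equal to 100 iff every member is best-extracted there. Missing or
  not-detected members are a hard error by default; the `zero` policy scores
  them 0 as a conservative lower bound. The practical question "which
  polymer for this complex?" is answered by ranking this index.
* **Replicate R²** is the squared Pearson correlation between the two
  biological replicates' per-protein mean intensities, computed on log10 of
  proteins positive in both (LFQ spans decades; the linear scale would be
  dominated by a handful of abundant proteins). The transform is recorded in
  the report.
* **Stratification** bins best-solubilized proteins with left-closed,
  right-open edges: MW {<40, ≥40 kDa}, TMD {0, 1–5, >5}. Both
  within-condition and within-bin fractions are emitted, since either
  normalization is a legitimate reading of a population plot.
* **Condition clustering** is agglomerative (average linkage) on correlation
  distance between condition vectors, with not-detected cells excluded
  pairwise (shared absence must not manufacture similarity; pairs sharing
  < 3 proteins get the maximal distance 2). Conditions are sorted before
  clustering so the result is independent of input column order. The
  dendrogram exports as Newick with heights converted to branch lengths.

## Photobleaching analysis

Step counting fits a piecewise-constant signal by exact penalized
least-squares segmentation (optimal partitioning via dynamic programming,
O(T²) per trace). The penalty is `3 · σ̂² · log T`, with σ̂ a robust noise
scale from the median absolute deviation of first differences — steps are
sparse outliers there, so σ̂ is unbiased by the staircase itself. The factor
3 (1.5× the BIC factor) suppresses spurious change-points while keeping a
single-frame intermediate level detectable at step/noise ≥ ~5; at that SNR
exact-step accuracy on simulated traces is ≈ 98–99%, with the residual
errors dominated by two bleaching events landing on adjacent frames.
Segments whose means fail the monotone-decrease constraint are merged before
counting, since photobleaching cannot gain intensity. Counting is invariant
to positive rescaling of the trace because the penalty scales with σ̂².

Maturation correction: a GFP matures to fluorescence with probability
`p_mat`, so an m-mer shows k ~ Binomial(m, p_mat) fluorescent copies, and a
fully dark particle (k = 0) is never captured by the anti-GFP surface. The
observed step histogram over captured particles is therefore the globally
renormalized mixture

    h_k = Σ_m π_m · C(m,k) p^k (1−p)^{m−k} / Z,   Z = Σ_m π_m (1 − (1−p)^m).

Fitting the unnormalized binomial columns by non-negative least squares and
renormalizing the solution onto the simplex recovers the **all-particle**
copy-number distribution π, correctly re-inflating species that are more
likely to go entirely dark. (Inverting per-m zero-truncated columns instead
would return the captured-particle distribution — e.g. 0.455/0.545 for a
true 50/50 monomer/dimer at p_mat = 0.8 — a systematically different
quantity.) At p_mat = 1 the system is the identity and the estimate equals
the normalized histogram. The estimate is a valid probability vector by
construction. Confidence intervals are percentile bootstrap over particles
(200 multinomial resamples, seeded).

Defaults: K = 6 (monomer–tetramer observed in practice, two states of
headroom) and p_mat = 0.8, a common literature value for eGFP; p_mat has no
universally agreed value, so the CLI makes it a mandatory explicit flag and
every result records the value used.

## Problem sizes and determinism

The built-in verification runs use 300–500 proteins × 13 conditions × 8
replicates for the screen, 1 000-point grids for the quench assay, and
500–1 500 particles for photobleaching — sizes at which every recovery
statistic is well-resolved while a full run of the suite plus the
acceptance script completes in seconds. Every stochastic component takes an
explicit integer seed and is bit-reproducible; there is no global random
state anywhere in the package.

## Known limitations

* The organelle vocabulary is a fixed label set; real UniProt subcellular
  annotation is richer and version-dependent.
* Protein groups are treated as atomic; isoform expansion and shared-peptide
  ambiguity are out of scope.
* The step counter assumes piecewise-constant traces; blinking, drift and
  partial bleaching are not modeled (and are not generated).
* The maturation inversion is ill-conditioned for large K at low p_mat;
  with K = 6 and p_mat ≥ 0.7 the mixing matrix condition number is < 10,
  which is why K is capped rather than free.
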