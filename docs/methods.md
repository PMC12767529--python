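# Methods

`memascreen` implements the statistical analysis of a microenvironment
microarray (MEMA) screen: printed spots of ECM proteins in multiwell
plates, a soluble ligand per well, cells grown on the spots, and per-cell
image features (DAPI, EdU) as the raw readout.  One ECM x ligand pair is a
MEP (microenvironment perturbation).  This note records the models,
defaults and design choices, and what the synthetic benchmark does and
does not establish.

## Data model and design conventions

Spots are addressed by (plate, well, array, row, col); arrays are
identifiers nested in wells (one array per well on 8-well plates, but the
model does not rely on that).  MEP identity is the (ECM name, ligand name,
ligand concentration) triple, so print-concentration variants of an ECM
are distinct entries unless the caller collapses them.  Rows/columns are
0-based on a rectangular print grid; failed spots are simply unassigned
addresses.

The control convention is that the PBS "ligand" paired with each ECM forms
that ECM's control MEP and PBS control spots are present in **every well
used for testing**.  This is a statistical necessity, not a convenience:
each ligand occupies a few whole wells, so a control condition confined to
its own wells would be confounded with array-level batch effects, and no
normalization could separate a ligand effect from the batch draw of its
wells.  In-well controls anchor every array to the same baseline.  On the
physical platform these correspond to vehicle/reference spots printed in
the same layout on every array.

The canonical layout used by the simulator and tests doses each treatment
ligand into 3 wells and prints 5 spots per ECM per array (15 replicate
spots per MEP, matching the screen's ~15 replicates) plus 2 PBS control
slots per ECM per array; the slot-to-position map is one seeded shuffle
shared by all arrays, as a printing robot produces.

## Synthetic screens

The generator emulates the screen's statistical structure, not its images:

* **Spot counts** — negative binomial with mean
  `mu = baseline * ecm_effect * ligand_effect * array_factor *
  exp(surface(row, col))` and size (dispersion) `theta`, so
  `var = mu + mu^2/theta`.  Defaults: baseline 40 cells/spot (typical of
  MEMA spots), `theta = 5` (replicate CV of roughly 50%, counting plus
  adhesion noise).
* **Array batch effects** — multiplicative on counts / additive on log
  scale, drawn log-normally with log-sd 0.15 per array (a ±15% well-to-well
  swing; the screen data themselves do not quantify this, so it is a
  convention flagged here).
* **Spatial artifacts** — an additive surface on the log scale over the
  print grid, chosen from planar gradient, centered Gaussian bump, or
  low-order polynomial; default a mild planar gradient (0.04/row,
  -0.03/col, centered).
* **EdU** — per-cell positive label from a logit model
  (base rate 0.30 plus per-ligand shift), intensity log-normal from the
  matching component of a two-component mixture (log-means 5.0/7.0, log-sd
  0.5; a 4-sigma separation, ~2% irreducible misclassification).  The
  generator warns when the components' Bhattacharyya coefficient exceeds
  0.26, the overlap at which the Bayes error of any gate passes ~5%.

Everything planted (true labels, spot means, array factors, surface
values) is returned in a ground-truth record, so recovery can be scored
exactly.  All draws flow from a single integer seed.

What the generator does **not** emulate: segmentation errors, cell
morphology beyond scalar intensities, dose-response across ligand
concentrations, spot dropout or printing defects (representable as
unassigned addresses but not generated), and spatial structure in the EdU
signal.  Passing the synthetic benchmark therefore shows the pipeline's
statistical machinery is correct under the assumed noise model, not that
the assumed model exhausts real screen data.

## EdU gating

Gates are fit on natural-log intensities, per array by default
(illumination varies array to array; per-plate and global scopes are
config options).  The default method fits a two-component Gaussian mixture
and cuts at the equal-posterior point between the component means; if the
fit degenerates (components closer than half a standard deviation, or one
weight below 2%) it falls back to Otsu's threshold.  A scope group with
identical intensities is labeled all-negative with a warning; fewer than
two cells is an error.  Gating on the log scale makes labels invariant to
multiplicative intensity rescaling.

## Spot summarization

Cell count is the number of segmented nuclei at the address; the
EdU-positive proportion is labeled-positive over count (missing for empty
spots, which are retained so replicate accounting stays auditable);
per-signal medians are plain sample medians (mean of the central pair for
even sizes).  Cells at addresses missing from the design are an error, not
silently dropped.

## Normalization

Signals are normalized independently on additive scales: `log(count+1)`
for cell counts, the empirical logit `log((k+0.5)/(n-k+0.5))` for EdU
proportions, natural log for intensity medians.  Counts and per-cell
labels themselves are never altered; normalized values live in `*_norm`
columns.

**RUV.**  Per plate (default; per-experiment available), each signal is
arranged as an arrays x spot-positions matrix.  The negative controls are
the residuals after subtracting each entry's replicate-group median (the
other spots carrying the same MEP); replicate groups span rows and columns
because a MEP's spots sit in several wells.  The top-k left singular
vectors of the residual matrix are per-array scores of unwanted variation;
after column-centering, their least-squares projection is removed from
every column of the full matrix.  `k = 0` is the identity; default
`k = 1` (one dominant batch axis per plate — well-to-well intensity level;
the fit records singular values so a scree check is available in the
diagnostics JSON).

**Bivariate LOESS.**  Per array, the RUV-normalized signal is fit by
locally weighted linear regression on (row, col): for each spot the
`ceil(span*n)` nearest neighbours weighted by the tricube kernel, default
span 0.5 and local-linear degree (exact for planar gradients).  The
corrected value subtracts the fitted surface and adds back the array grand
median, so array-level location set by RUV is preserved.  Arrays with
fewer than 20 finite values are passed through with a warning.  Masked
(missing) entries are excluded from all statistics and never imputed.

## Hit calling

Replicate spots of each MEP are median-summarized for reporting.  The
significance test is Dunnett's many-to-one comparison of each ligand
against the PBS controls on normalized values: pooled within-group
variance, `df = N - (g+1)`, and the adjusted p from the joint g-variate t
distribution of the statistics.  Because all statistics share the control
mean, the correlation is the product form `rho_ij = lambda_i lambda_j`
with `lambda_i = sqrt(n_i/(n_i+n0))`; the family-wise probability
`P(max|T_i| >= t)` reduces to a 2-D integral over the shared control
variate and the pooled-variance chi variate, evaluated by 48x48
Gauss-Hermite x Gauss-Legendre quadrature.  Adjusted p-values are
deterministic for balanced and unbalanced designs (accuracy ~1e-8;
agreement with R `multcomp` to 1e-8 and scipy's QMC implementation to its
own Monte-Carlo error).

Two family layouts are provided: per-ECM strata (each ECM family tested
against its own PBS spots; error controlled within each family) and pooled
(per-ECM medians centered out, one family per screen; this is the layout
used when screen-level false-call rates are calibrated).  Two-sided tests
and alpha = 0.05 by default.

The observational unit is configurable.  `unit="spot"` uses every
normalized spot value — replicate-level degrees of freedom, appropriate
when array variation has been fully removed.  `unit="array"` first
median-summarizes to one value per ligand per array.  Arrays are the
independently perturbed physical unit: spots within a well share whatever
array-level variation survives normalization, and treating them as
independent understates the variance of ligand means (each ligand occupies
only a few wells) and inflates the family-wise error.  RUV estimates each
array's factor from only a few dozen spots against spot-level noise, so
some residual array variance is unavoidable; the array-level unit keeps
the test honest regardless, at the price of fewer degrees of freedom, and
is what the end-to-end false-positive calibration uses.  Ranked outputs
break ties by adjusted p, then |estimate|, then name.

## Growth-assay metrics

Caliper tumour volume `width^2 * length / 2`; luminescence trend
`radiance_t / baseline` with final growth ratio
`100 * (radiance_final - baseline) / baseline` (%); confluence as
percentage of the first timepoint; clonogenic potential as treated/control
optical density.  The GR metric follows the growth-rate-corrected
framework of Hafner et al. (Nat Methods 13:521, 2016):
`GR(c) = 2^(log2(x_c/x0) / log2(x_ctrl/x0)) - 1`, requiring a growing
control.  GR50 inverts a 3-parameter sigmoid
`GR(c) = GR_inf + (1 - GR_inf)/(1 + (c/GEC50)^h)` fitted by least squares
in log-concentration parameterization with three deterministic starts
(GEC50 initialized at the low, middle and high tested concentrations);
constraints `GR_inf in [-1, 1]`, `h in [0.1, 10]` are conventions.  GR50
is "not reached" when the fitted plateau stays above 0.5 or the crossing
falls outside the tested range widened 10-fold each way.

## Numerical and benchmark choices

Benchmarks run at desk scale: 8–12 treatment ligands x 4 ECMs x 15
replicate spots (~670 spots, ~27k cells per screen); the full 1,575-MEP
design is exercised for enumeration and report-shape checks only.  The
false-positive calibration simulates 1,000 independent null screens
(ligand effects 1, EdU shifts 0, artifacts on) through the entire
pipeline and scores the fraction of screens with any ligand called at
alpha = 0.05 against the nominal level plus three binomial standard
errors.  Planted-recovery checks use a 0.5x–2x graded effect ladder
(Spearman rank agreement) and an exactly-3-planted 2-fold screen
(top-ranked recovery).

Known limitations: LOESS assumes the artifact surface is smooth at the
span scale (sharp printing defects are better handled as masked spots);
RUV with k=1 targets one batch axis and leaves higher-rank structured
noise; the Dunnett model assumes equal within-group variances on the
normalized scale (the empirical-logit transform keeps proportions
near-homoscedastic away from 0/1); and hit identities from the original
screen are not reproducible because the raw data are not deposited — only
the procedure is validated, on synthetic ground truth.
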