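# Methods notes

This note records the models behind each analysis stage, the defaults
and why they were chosen, the numerical decisions that matter, what the
synthetic-data generator does and does not emulate, and known
limitations.

## Units and data layout

All computation uses molar concentrations, seconds, rates in s⁻¹ and
M⁻¹s⁻¹. Conversion from nM/µM and minutes happens exclusively in the
CSV readers, which accept per-row unit columns; a single internal
convention removes a whole class of silent errors when assays mix unit
scales. Inputs are long/tidy CSVs (one measurement per row) with
explicit grouping keys (ligand, receptor, pathway, replicate); wide
plate layouts are out of scope.

## Dose–response

Normalization maps each (receptor, pathway) group to a percent scale:
basal wells (dose = 0, or a designated basal ligand) define 0%, the
mean response of the reference agonist at its top dose defines 100%.
Zero-dose rows are therefore allowed in datasets and are used only as
basal anchors, never as fit points.

The 4PL is parameterized in logEC₅₀ with the slope constrained positive
through log-parameterization. Fits use Levenberg–Marquardt from 7
log-spaced EC₅₀ starts across the observed dose range; the best RSS
wins, with ties broken by the slope closest to 1 — fully deterministic.
Standard errors come from the Gauss–Newton covariance
(JᵀJ)⁻¹·RSS/dof, which is what commercial fitters report; no bootstrap
by default. Degenerate inputs (flat curves) return a non-converged fit
with an `unidentifiable_flat` status rather than raising, so batch runs
continue past bad wells. Replicates are pooled as individual points
into one fit by default; per-replicate fitting followed by averaging
can be done by the caller on subsets, but pooled fits are the package's
reported values.

The real-time cAMP pipeline extracts a rate constant per agonist
concentration by single-exponential fit inside a configurable window
(default 5–305 s, matching how such biosensor traces are usually
trimmed to avoid mixing/injection artifacts and late-time drift), then
fits the 4PL to (concentration, rate) pairs. The stage-2 slope is left
free. Traces with no identifiable rate are excluded with a warning
provided at least four concentrations survive.

## Operational model and bias

Em and the transducer slope n are shared per (receptor, pathway); per
ligand either log(τ/K_A) (full agonists, reduced form) or
(log τ, log K_A) (partial agonists) are fitted. The full/partial switch
sits at 90% of the largest observed plateau in the group (configurable):
for a full agonist the data constrain only the ratio τ/K_A, and trying
to fit both parameters produces an unidentifiable ridge. The reduced
form is the τ→∞, A≪K_A limit of the full model. When every ligand in a
group is full, Em itself is unidentifiable and is anchored to the
reference plateau with an explicit status note.

The transducer slope is initialized at 1 and clipped to [0.3, 3] inside
the optimizer — slopes outside that range in this assay family indicate
a misfit rather than biology, and the bounds stabilize the global fit.
Starting values come from per-curve 4PL fits (EC₅₀ → K_A/τ composites,
plateau → τ via plateau = Em·τⁿ/(1+τⁿ)).

SEs of log(τ/K_A) use the joint fit covariance (delta method on
log τ − log K_A for partial agonists). Across pathways the reference
coefficient is treated as independent, so Δ and ΔΔ errors combine in
quadrature; this is mildly conservative because the two pathway fits
are genuinely independent data sets here.

Identities enforced (and tested) exactly: RE = 10^Δ,
bias factor = 10^ΔΔ, self-comparison = 1, pathway swap inverts the
factor, within-fit chain rule Δ(A,C) = Δ(A,B) + Δ(B,C).

## Equilibrium binding

Saturation: with matched nonspecific wells, specific = total −
nonspecific is fitted to the hyperbola; without them a one-step model
adds a linear nonspecific term. The linear term is re-parameterized as
the nonspecific signal at the top concentration so that all three
parameters live on comparable numeric scales — fitting the raw
slope (units of signal per molar, ~10⁸–10⁹) stalls the optimizer. A
fitted K_D more than 10× above the highest tested concentration is
flagged `kd_unidentifiable` (no curvature in the data).

Competition: descending 4PL in log concentration, free slope by
default. Ki conversion assumes one-site competition, so a fitted slope
outside [0.8, 1.2] attaches a caveat flag to the result; a positive
dose–binding correlation flags non-monotonic displacement. Ki is
computed only when the per-experiment radioligand concentration and K_D
are supplied — the radioligand concentration varies between plates and
must travel with the data, not be a package constant.

## Competition kinetics

The closed form for bound labeled ligand uses the standard two-ligand
mass-action solution with eigenvalues K_F, K_S derived from
K_A = k₁L + k₂, K_B = k₃I + k₄ and the coupling term 4k₁k₃LI. When the
eigenvalues coalesce (|K_F − K_S| < 10⁻⁹·K_F) the removable singularity
is evaluated by its analytic series limit

    RL(t) = C·[k₄/K²·(1 − e^(−Kt)) − t·(k₄ − K)/K·e^(−Kt)],  K = (K_F+K_S)/2,

rather than by jittering parameters — deterministic and testable. The
ODE oracle integrates the same system with LSODA at rtol 10⁻¹⁰ and is
documented as the reference implementation; closed form and oracle
agree to better than 10⁻⁶ of Bmax across random parameter draws
spanning three orders of magnitude per rate (the test bound is 0.1%).

The global fit shares (k₃, k₄, Bmax) across association traces, with
rates log-parameterized and starts spanning a grid of plausible kinetic
K_D values bracketing the competitor concentrations. The radioligand's
own rates are fixed inputs, never co-fitted — they come from a separate
experiment, and co-fitting them would absorb competitor information
into the wrong parameters. Datasets containing only competitor-free
traces raise an identifiability error (k₃, k₄ do not enter the model;
the profile likelihood is flat). Nonspecific binding in association
traces is assumed removed by the filtration washes (additive constant
default 0).

Dissociation traces fit y = ns + (y₀ − ns)e^(−k_off·t); a net-rising
trace is rejected via the sign of the fitted amplitude.

## Structure metrics

Parsing keeps the first model only and resolves altlocs to the
highest-occupancy conformer (ties prefer 'A'). Hydrogens are retained
in the model but excluded from B-factor statistics. Selectors use
author (PDB) chain/residue numbering; Ballesteros–Weinstein labels are
documentation only, since mapping them requires alignment machinery out
of scope here.

Cα RMSD matches residues by (chain, number, insertion code)
intersection inside a user-supplied chain/range selection and
superposes by orthogonal Procrustes with a determinant guard against
improper rotations (a mirrored structure must not superpose to zero).
Restricting to the receptor chain and excluding fusion-partner and
nanobody chains is the caller's responsibility via the selection.

Residue B-factor is the unweighted mean over the residue's non-hydrogen
atoms (Cα-only offered as an option); the overall B-factor is the mean
over all selected non-hydrogen atoms, so the atom-count-weighted mean
of normalized values is exactly 1 — a tested identity. Deltas between
two profiles carry a sign classification (decreased/increased/
unchanged) mirroring the blue/red coloring convention for stabilization
maps.

## Synthetic data

Each generator draws from the exact forward model its analysis stage
fits, adds additive Gaussian noise on the signal scale (no error model
is published for these assays; heteroscedastic options are deferred),
and writes ground truth to a separate `truth.json` sidecar so fits can
never see it through the data schema. A fixed spec + seed yields
byte-identical files.

Default designs follow the study conditions: dose series 10⁻¹⁰–10⁻⁴ M
in duplicate; saturation around K_D = 0.080 nM with Bmax 2.7 (the β₂AR
membrane values; the β₁AR pair 0.125 nM / 4.3 appears in tests);
competition at 0.25 nM radioligand in triplicate; association kinetics
with a competitor-free trace plus a 1:3:10 concentration ladder read
over one hour. The ladder's absolute scale is set by the competitor's
kinetic K_D (k₄/k₃ = 5 nM for the default synthetic competitor) so that
partial competition keeps both rates identifiable. The synthetic
radioligand rates (k₁ = 5×10⁷ M⁻¹s⁻¹, k₂ = 5×10⁻³ s⁻¹, K_D 0.1 nM) are
plausible for a high-affinity antagonist radioligand but are synthetic
stand-ins: real analyses must supply independently measured values.
The default reference agonist is generated with log τ = 2.5 — a genuine
full agonist (plateau 99.7% of Em) — so the reduced-form treatment of
the reference introduces no structural error into recovered
coefficients. The built-in cross-pathway bias of the default
two-pathway spec is ΔΔlog(τ/K_A) = 0.7.

The structure generator emits a toy polyalanine helix (N, CA, C per
residue) with controllable per-residue B-factors, optional rigid
transforms and coordinate noise. It exists to exercise the metric code
paths deterministically; it does not resemble receptor geometry, and
passing structure tests on it says nothing about chain-matching
subtleties of real deposited files (validated separately against
deposited coordinates when network access allows).

What passing recovery tests shows — and does not. The generator's noise
is i.i.d. Gaussian on the signal scale; real plate data have
replicate-level correlation, edge effects, and occasional gross
outliers. Parameter-recovery results here demonstrate the estimators
are correct and calibrated under the stated error model, not that they
are robust to artifacts the model excludes.

## Problem sizes

Monte-Carlo studies use 100 seeds for the 4PL and bias-pipeline
recoveries and 200 seeds for competitor-rate recovery and operational
SE calibration — enough to pin medians and means well inside the
asserted bounds while keeping the full suite and the acceptance script
each under a minute of compute.

## Known limitations

- No biphasic/two-site dose–response or competition models; no Schild
  analysis; no allosteric ternary-complex binding models.
- No kinetic (time-dependent) bias measures or alternative bias scales.
- No ligand-depletion or two-state isomerization kinetic schemes.
- Structure module: no electron-density handling, no automated
  Ballesteros–Weinstein numbering, no trajectory readers.
- The operational fit treats replicates as pooled points; hierarchical
  (per-experiment) bias estimation is not implemented.
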