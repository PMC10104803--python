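# betapharm

Quantitative pharmacology toolkit for GPCR subtype-selectivity studies,
built around the assays used to characterize catecholamine agonists at
the β₁- and β₂-adrenergic receptors: dose–response analysis,
operational-model quantification of ligand bias, equilibrium and
kinetic radioligand binding, and structure-derived binding-pocket
metrics — plus a seeded synthetic-data generator that makes every stage
testable against known ground truth.

## Who this is for

Receptor pharmacologists who run plate-based signaling assays
(β-arrestin recruitment, cAMP/IP-one accumulation), radioligand binding
experiments, and structural comparisons, and who want the fitting and
bias arithmetic in one scriptable, reproducible package instead of a
chain of spreadsheet/Prism steps.

## The models

**Dose–response (4PL).** Raw signals are normalized per
(receptor, pathway) group to basal activity (0%) and the maximal effect
of a reference full agonist (100%), then fitted with the
four-parameter logistic

```
E(A) = basal + (Emax − basal) / (1 + 10^(n·(logEC50 − log10 A)))
```

by multi-start least squares. Real-time second-messenger traces are
reduced to rate constants with single-exponential fits (default window
5–305 s); the rate-vs-concentration relation is itself fitted with the
4PL (two-stage pipeline).

**Operational model and bias.** Per pathway, all ligands are fitted
jointly to the operational model of agonism

```
E(A) = Em · τⁿ Aⁿ / ((A + K_A)ⁿ + τⁿ Aⁿ)
```

with Em and the transducer slope n shared. Full agonists (plateau ≥ 90%
of the group maximum) use the reduced form in which only the
transduction coefficient log(τ/K_A) is identifiable; partial agonists
carry separate log τ and log K_A. Comparing a test agonist with the
reference gives Δlog(τ/K_A) and the relative effectiveness
RE = 10^Δ within a pathway; comparing the Δs across two pathways gives
ΔΔlog(τ/K_A) and the bias factor 10^ΔΔ (1 = unbiased). Standard errors
propagate by the delta method within a fit and in quadrature across
subtractions.

**Radioligand binding.** Saturation data follow the one-site hyperbola
Bmax·L/(K_D + L) (nonspecific binding subtracted from matched wells or
modeled as a linear term); competition curves are fitted with a
descending logistic, and IC₅₀ converts to the inhibition constant via
Cheng–Prusoff, K_i = IC₅₀ / (1 + [L]/K_D).

**Kinetics of competitive binding.** The time course of bound labeled
ligand in the presence of an unlabeled competitor follows the
closed-form two-ligand mass-action solution (Motulsky–Mahan); a global
fit across association traces at several competitor concentrations
recovers the competitor's on/off rates k₃ and k₄ with the radioligand's
own rates fixed from an independent experiment. An explicit ODE
integration of the same mass-action system serves as the independent
oracle. Propranolol-chase style dissociation traces give k_off from a
single-exponential decay with a nonspecific plateau.

**Structure metrics.** PDB/mmCIF coordinates (parsed with gemmi) feed
atom-pair distances (e.g. the V3.36 Cα – F45.52 Cζ pocket width),
residue-matched Cα RMSD after optimal rigid superposition (SVD with
reflection guard), per-residue B-factors normalized by the overall
receptor B-factor with between-structure deltas, and four-atom torsion
angles.

## Worked example

Generate a two-pathway synthetic dataset with a built-in cross-pathway
bias of ΔΔlog(τ/K_A) = 0.7 (bias factor 10^0.7 ≈ 5.01) at 2% noise,
then run the full bias pipeline:

```python
from betapharm import (read_dose_response_csv, normalize, fit_operational,
                       transduction_coefficients, cheng_prusoff)
from betapharm.operational import bias_table
from betapharm.simulate import SyntheticSpec, generate

spec = SyntheticSpec(seed=42, assay_kind="dose_response_operational",
                     noise={"model": "gaussian", "sigma": 2.0,
                            "scale": "percent_of_max"})
paths = generate(spec).write("example_data")
dataset = read_dose_response_csv(paths["dose_response"])
curves = normalize(dataset, reference_ligand="ref")
coeffs = []
for pathway in ("arrestin", "camp"):
    params = fit_operational([c for c in curves if c.pathway_id == pathway],
                             reference_ligand="ref")
    coeffs.extend(transduction_coefficients(params))
for c in coeffs:
    print(f"log(tau/KA)[{c.ligand_id}, {c.pathway_id}] = "
          f"{c.log_r:.3f} +/- {c.se_log_r:.3f}")
res = bias_table(coeffs, "ref", "arrestin", "camp")[0]
print(f"ddlog(tau/KA) = {res.delta_delta_log_r:.3f} "
      f"+/- {res.se_delta_delta_log_r:.3f}")
print(f"bias factor   = {res.bias_factor:.2f}")

ki = cheng_prusoff(ic50=3.5e-9, radioligand_conc=0.25e-9,
                   radioligand_kd=0.125e-9)
print(f"Ki = {ki*1e9:.4f} nM")
```

Output:

```
log(tau/KA)[ref, arrestin] = 7.510 +/- 0.021
log(tau/KA)[test, arrestin] = 7.296 +/- 0.075
log(tau/KA)[ref, camp] = 7.496 +/- 0.022
log(tau/KA)[test, camp] = 6.522 +/- 0.085
ddlog(tau/KA) = 0.760 +/- 0.117
bias factor   = 5.75
Ki = 1.1667 nM
```

The transduction coefficients in the two pathways differ for the test
ligand but not the reference; their double difference (0.760 ± 0.117
for this seed, truth 0.7) exponentiates to the bias factor. The Ki line
is the Cheng–Prusoff conversion of a 3.5 nM IC₅₀ measured at 0.25 nM
radioligand against a 0.125 nM-K_D radioligand.

The same stages are available from the shell via the `betapharm` CLI
(`simulate`, `fit-dose-response`, `fit-bias`, `fit-saturation`,
`fit-competition`, `fit-kinetics`, `structure-metrics`), each taking
`--config/--seed/--out/--log-level` and writing a JSON report plus a
readable table.

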