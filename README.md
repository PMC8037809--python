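# bbbperm

Estimation of blood–brain-barrier (BBB) permeation for small molecules —
developed around four plant-derived triterpenoid saponins (arjunic acid,
akebia saponin D, bacoside A, platycodin D) — by combining biomimetic
liquid-chromatography measurements with QSAR prediction.

The package is for pharmacokinetics / medicinal-chemistry researchers who
screen compounds for CNS penetration before any in vivo work: it turns raw
isocratic HPLC retention times from membrane-mimicking systems into logBB
estimates, compares them with in silico profiles, and supports rebuilding
the underlying QSAR model on new training data.

## What it computes

**logBB** is the log10 steady-state brain/blood concentration ratio,
`logBB = log(C_brain / C_blood)`. The core model is an affine QSAR:

```
logBB = −0.114 − 0.098·ΔlogP + 0.278·logPow + 0.218·E
```

with ΔlogP = logPow − logPcw (hydrogen-bonding capacity), logPow the
n-octanol/water lipophilicity and E the Abraham excess molar refraction
(n = 40 training compounds; reported R²_CV = 78.25%, R²_pred = 74.02%,
s = 0.436).

Three chromatographic lipophilicity surrogates can replace logPow in that
equation, each obtained by fitting log10 k (retention factor
k = (t_R − t_0)/t_0) against the eluent composition and extrapolating to
pure water (**logkw**):

* **IAM** — immobilized-artificial-membrane (phosphatidylcholine) column,
  acetonitrile fraction 0.3–0.6 v/v;
* **CHOL** — cholesterol-bonded column, same eluent design;
* **BMC** — bio-partitioning micellar chromatography with Brij35 micelles,
  total surfactant 0.075–0.15 mol/dm³, abscissa C_M = C − CMC.

From the BMC data the Foley linearization

```
1/k = (K_MA / (P_SW·Φ)) · C_M + 1 / (P_SW·Φ)
```

yields the analyte–micelle association constant **K_MA** (dm³/mol) and the
stationary-phase/water partition coefficient P_SW; log10 K_MA is exposed as
an additional BBB-permeation descriptor. Profile aggregation collects every
logBB variant per compound, compares methods pairwise, and issues a
qualitative permeant / non-permeant / uncertain call (logBB ≥ 0 / ≤ −1,
with TPSA ≥ 90 Å², MW and logPow appended as supporting evidence).

Model building on training tables uses OLS with backward elimination,
leave-ten-out cross-validation (PRESS, RMSECV, R²_CV) and a leverage
applicability domain (h* = 3(p+1)/n). Matching synthetic-data generators
make every stage testable end to end.

## Worked example

```python
import bbbperm as b

# in silico profiles + descriptors of the four reference saponins
insilico = b.load_reference_insilico()
profiles = b.build_profiles(insilico=insilico,
                            descriptors=b.load_reference_descriptors())
for p in profiles:
    print(p.compound_id, b.classify_permeability(p).call)

permeant = [r for r in insilico if r.logbb is not None and r.logbb >= 0]
print("mean logPS_Fubrain:", b.mean_descriptor([r.logps_fubrain for r in permeant], 2))
print("max Fb:", b.extreme_fraction(insilico, "fb_brain", "max"))

# biomimetic logBB: substitute a CHOL logkw for logPow in the QSAR model
model = b.published_model()
print(b.predict_logbb(model, 1.171, 5.2, 1.0))  # logPow route
```

prints

```
Arjunic acid permeant
Akebia saponin D permeant
Bacoside A permeant
Platycodin D non_permeant
mean logPS_Fubrain: -5.03
max Fb: ('Platycodin D', 0.98)
1.4348420000000002
```

i.e. three of the four saponins are predicted to cross the BBB, platycodin D
is not (its in silico logBB is an upper bound at −2); the three permeant
compounds share a brain/plasma equilibration rate around −5.03, and
platycodin D has the largest unbound brain fraction (0.98). The last line is
the QSAR logBB of arjunic acid assuming E = 1.

A fitted rebuild looks like statsmodels:

```python
table = b.simulate_qsar_table(b.QSARSimSpec(seed=0))
res = b.LogBBRegression(table).fit(method="backward", alpha=0.10)
print(res.summary())
```

The command line mirrors the same stages
(`bbbperm simulate|logkw|foley|train|predict|profile --help`).

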