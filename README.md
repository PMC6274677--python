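# hydromelt

Protein-hydration analysis from wide-line ¹H NMR melting diagrams.

## The problem

When an aqueous protein solution is frozen and slowly warmed through
equilibrium states, the water molecules bound to the protein surface
start to rotate well below 0 °C — each one at the temperature where the
thermal energy overcomes the potential barrier binding it.  Wide-line
¹H NMR sees this directly: mobile water protons produce a slowly
decaying (motionally narrowed) component in the free induction decay
(FID), and the slow-component amplitude extrapolated to *t* = 0 counts
them through the nuclear magnetization *M*₀ ≈ *nB*₀/*T*.

Plotting the mobile-water fraction *n* against temperature gives the
**melting diagram (MD)** — a fingerprint of the protein's hydration
shell.  On the dimensionless **normalized fundamental temperature**
scale, *T*_fn = *T*/273.15 (thermal energy normalized to the melting
point of ice), the MD of a globular protein shows

1. a sharp onset step where the almost identically bound first-shell
   waters mobilize together,
2. a flat plateau [*T*_fno, *T*_fne] — no new water mobilizes: the
   first shell is energetically homogeneous, and
3. a heterogeneous rise toward *T*_fn = 1 described by a short power
   series
   *n* = *A* + *B*(*T*_fn − *T*_fn1) + *C*(*T*_fn − *T*_fn2)².

The derivative Δ*n*/Δ*T*_fn (the **differential melting diagram, DMD**)
is the distribution of potential-energy barriers of protein–water
bonds.  The Waugh–Fedin relation *E*₀ = *c·R·T*, with *c* ≈ 2.65
calibrated from the latent heat of ice (6.01 kJ/mol at 273.15 K), turns
temperatures into activation energies in kJ/mol.

Three order parameters classify ordered vs. intrinsically disordered
proteins (IDPs):

| parameter | definition | meaning |
|---|---|---|
| HeR  | (1 − *T*_fne)/(1 − *T*_fno) | heterogeneous share of the bound-water energy range (0 = bulk-water-like, 1 = no plateau, IDP limit) |
| HeRn | *n*_he/(*n*_he + *n*_ho) | heterogeneous share of the bound-water *count* |
| HeM  | (*B* + 2*C*)/(1 − *T*_fne) | slope-like (tangent-like) heterogeneity measure, unbounded |

*n*_ho (first-shell waters, the plateau average) and *n*_he (waters in
the heterogeneous region, read near *T*_fn ≈ 1) convert to waters per
protein molecule via the water/protein molarity ratio.

The package is aimed at people who run wide-line NMR (or have reduced
melting-diagram tables) and want the full chain — FID decomposition,
Curie 1/T correction, MD assembly, segmented model fit, DMD, order
parameters — with explicit tolerances, uncertainties, and a synthetic
ground-truth generator to validate every stage.

## Worked example

Simulate a globular-protein-like melting diagram (35 temperatures from
−70 to −1 °C, Gaussian noise s.d. 0.002 on *n*), analyze it, and render
the characteristic-quantities row:

```sh
$ hydromelt simulate --preset ubiquitin_like --seed 7 --out sim
wrote sim/md.csv (35 points) and truth.json

$ cat > ubq.json <<'EOF'
{"protein_name": "UBQ", "concentration_mg_ml": 50.0,
 "molecular_weight_da": 8565.0, "residue_count": 76}
EOF

$ hydromelt analyze --md sim/md.csv --spec ubq.json --out run --seed 7
onset 0.8292  plateau [0.8329, 0.9690]  A=0.01767  HeR=0.19  HeRn=0.43

$ hydromelt report run/fit.json run/hydration.json --name UBQ
protein T_fno     T_fne     HeR      n_ho     n_he      HeRn     HeM
UBQ     0.833 (4) 0.969 (4) 0.19 (2) 168 (4)  >125 (19) 0.40 (4) 1.1e+03
```

Reading the output: melting of protein-bound water sets in at
*T*_fn ≈ 0.829 (−46.7 °C, i.e. an activation energy of ~5.0 kJ/mol);
1.8% of the water is mobile across the plateau (the homogeneous first
hydration shell, here ≈168 waters per protein molecule at 50 mg/mL);
the heterogeneous rise above *T*_fn ≈ 0.97 holds at least another
125 waters (a lower bound — points between −1 and 0 °C are unreliable
and excluded); HeR ≈ 0.19 says about a fifth of the bound-water energy
range is heterogeneous, the signature of a well-ordered globular
protein.  An IDP-like sample (`--preset erd10_like`) instead gives a
short plateau, a strong quadratic rise and HeR near 0.7; bulk water
(`--preset bulk_water_like`) collapses to a single step at *T*_fn = 1.

`analyze` writes `md.csv`, `fit.json` (all model parameters, standard
errors, tolerances, fit window), `dmd_analytic.csv` / `dmd_numeric.csv`
(the barrier distribution, model-derived and model-free), and
`hydration.json` (order parameters, water counts, excitation energies,
uncertainties, provenance).  `analyze --fids manifest.csv` runs the
same pipeline starting from raw time-domain FID traces instead of a
reduced MD table; `simulate --fids` produces such a series.

The same pipeline is available as a library:

```python
from hydromelt import presets, generate_md, fit_md, summarize, calibrate_c, SampleSpec

md = generate_md(presets("erd10_like", seed=0))
fit = fit_md(md)
params = summarize(fit, md, SampleSpec("ERD10", 50.0, 29400.0, 260), calibrate_c())
print(fit.t_fno, fit.t_fne, params.her, params.n_ho_count)
```

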