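# halokit

Halogen-bond contact surveys and QSAR/IC50 analysis for halogenated
kinase inhibitors.

## The scientific problem

Brominated benzotriazoles — from the parent benzotriazole (Bt) through
4,5,6,7-tetrabromobenzotriazole (TBBt) — are ATP-competitive inhibitors
of protein kinase CK2α, a pleiotropic Ser/Thr kinase and long-standing
cancer drug target. Their potency spans four orders of magnitude
(IC50 from 0.27 µM for TBBt to > 2 mM for Bt) and is governed by a
balance of hydrophobic bulk, the ionic state of the triazole proton,
and — debatably — halogen bonding between ring bromines and
electron-rich acceptor atoms in the binding pocket.

`halokit` implements the computational side of this analysis as a
tested, reusable pipeline, for structural bioinformaticians and
medicinal chemists working with halogenated ligand series:

* **Contact surveys** — parse protein–ligand complexes (PDB format),
  enumerate sigma-hole donors (C–X with X = Cl, Br, I) and acceptor
  sites (backbone carbonyl O, side-chain O/N/S, water O, aromatic π
  centroids), and extract every X…Acc contact within a distance
  threshold (default 4 Å) together with its flanking angles C–X…Acc
  and X…Acc–C.
* **Distance-distribution decomposition** — fit the empirical
  *cumulative* distribution of contact distances (no binning, no
  clustering) with a single normal CDF Φ((x−μ)/σ), or with the
  two-component mixture

      F(x) = (1 − w₂)·Φ((x−μ₁)/σ₁) + w₂·Φ((x−μ₂)/σ₂),

  whose broad component captures nonspecific van der Waals packing
  (μ₁ ≈ 3.34 Å, σ₁ ≈ 0.28 Å) and whose narrow component isolates
  putative halogen bonds (μ₂ ≈ 2.90 Å, σ₂ ≈ 0.04 Å). An
  Anderson–Darling normality test (both parameters estimated,
  small-sample adjusted) and acceptor-stratified geometry summaries
  complete the survey statistics.
* **Dose-response IC50 estimation** — fit scintillation counts c(x)
  at inhibitor concentrations x to the one-site model

      c(x) = C_min + (C_max − C_min) / (1 + x/IC50),

  by global optimisation (multistart or simulated annealing) with a
  variance-matched relative-residual loss.
* **QSAR** — ordinary least squares of log10(IC50) on molecular volume
  and pKa, or on the summed ab initio energies ΔG_diss + ΔG_solv(anion);
  PCA descriptor screening; binding-energy correlation with
  per-compound residuals; leave-one-out Q².
* **Synthetic data** — generators for every input (dose-response
  counts, truncated distance mixtures, toy 3D complexes with planted
  contact geometry, descriptor tables with known coefficients), each a
  pure function of its seed with the ground truth in a manifest.

The measured descriptor/activity table for the ten-compound
benzotriazole series ships with the package (`halokit.load_table1()`).

## Worked example

```python
from halokit import (build_matrix, fit_linear_qsar, load_table1,
                     gen_dose_response, fit_ic50, gen_contact_distances,
                     fit_binormal_cdf)

table = load_table1()
active = build_matrix(table, censor="exclude")   # drop the censored parent
fit = fit_linear_qsar(active, ["Vmol", "pKa"])
print(f"R2 = {fit.r2_:.3f}, F({fit.df_[0]},{fit.df_[1]}) = {fit.f_stat_:.1f}")

counts, _ = gen_dose_response(ic50=0.56, c_max=1000, c_min=100, cv=0.05, seed=42)
ic = fit_ic50(counts.concentration_uM, counts.counts, seed=0)
print(f"IC50 = {ic.ic50_:.3f} +/- {ic.se_ic50_:.3f} uM")

d, _ = gen_contact_distances(2000, seed=0)
mix = fit_binormal_cdf(d, seed=0)
print(f"broad N({mix.mu1_:.2f}, {mix.sigma1_:.2f}^2), "
      f"narrow N({mix.mu2_:.2f}, {mix.sigma2_:.3f}^2), w2 = {mix.w2_:.2f}")
```

prints

```
R2 = 0.958, F(2,6) = 68.9
IC50 = 0.579 +/- 0.033 uM
broad N(3.34, 0.28^2), narrow N(2.90, 0.041^2), w2 = 0.15
```

Reading: on the nine active brominated compounds, molecular volume and
pKa together explain 96% of the variance in log-activity (both
coefficients negative — bigger and less acidic means more potent); a
simulated triplicate assay at 5% count noise recovers the true IC50 of
0.56 µM within its standard error; and the survey-scale distance sample
cleanly separates into the broad van der Waals population and the
narrow short-contact population.

The same stages are available from the shell:

```bash
halokit simulate complex --seed 1 --out sim          # synthetic complex + manifest
halokit scan --pdb sim.pdb --ligand LIG --out contacts.tsv
halokit xstat --contacts contacts.tsv --out survey.json
halokit qsar --model vol-pka --censor exclude --out qsar.json
halokit ic50 --data dose.csv --out fit.json
halokit report --xstat-json survey.json --qsar-json qsar.json --out report.json
```

Exit codes: 0 ok, 2 usage error, 3 data error, 4 convergence failure.

## Layout

```
src/halokit/
  elements.py      van der Waals radius sets, acceptor taxonomy
  compounds.py     the 10-compound descriptor/activity table
  structure.py     PDB parsing, halogen sites, acceptors, contact scan
  distfit.py       CDF fits, Anderson-Darling, geometry statistics
  doseresponse.py  IC50 estimation
  qsar.py          linear activity models, PCA, LOO diagnostics
  simulate.py      synthetic-data generators
  report.py, cli.py
docs/methods.md    models, assumptions, numerical choices, limitations
```
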