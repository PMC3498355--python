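# Methods

This note records the models the package implements, the assumptions
behind them, the defaults and why they were chosen, and what the
synthetic-data generators do and do not emulate.

## Contact survey

### Donors, acceptors, geometry

A halogen bond is modelled as a directional contact between the sigma
hole of a covalently bound halogen (C–X, X ∈ {Cl, Br, I}) and an
electron donor. Donor sites are found by scanning hetero (ligand)
residues for halogen atoms; the bonded carbon is the nearest carbon of
the same residue within 2.1 Å (a halogen with no such carbon is kept in
the distance census but excluded from angle statistics, since C–X…Acc
is undefined). Acceptor sites are:

| class | atoms | anchor for X…Acc–C |
|---|---|---|
| backbone carbonyl O | polymer `O`/`OXT` | same-residue `C` |
| side-chain O/N/S | non-backbone O/N/S | nearest carbon ≤ 1.8 Å |
| water O | `HOH`/`WAT` oxygen | none |
| π system | His/Phe/Tyr/Trp ring centroid | none |

π acceptors are represented by the centroid of the aromatic side-chain
ring (both rings for Trp); the distance is X…centroid and the acceptor
angle is undefined. Whether π centroids enter the fitted distance
distribution is controlled by the scan's `include_pi` flag; the default
includes them in the census, and the distance fits operate on whatever
contact table they are given.

Scan threshold: 4.0 Å by default. Halogen-bond classification is a
strict cutoff d < 3.7 Å — the sum of bromine and oxygen van der Waals
radii in the calibrated radius set (see below), i.e. the distance at
which the nonspecific packing population ends. Contacts are reported
per chain; multiple protein copies in an asymmetric unit are scanned
independently. Hydrogens are ignored; for alternate conformations the
highest-occupancy conformer is kept, ties broken toward altloc `A`
(the file's first conformer). Coordinates are Å, angles degrees,
residue numbering as in the source file.

Two van der Waals radius sets ship: `bondi` (standard Bondi values,
r(Br)+r(O) = 3.37 Å) and `paper` (Bondi rescaled uniformly so
r(Br)+r(O) = 3.70 Å, matching the survey cutoff). The calibrated set is
the default because the 3.7 Å ceiling is what the survey statistics are
defined against; the choice only relabels radii, never distances.

### Distance-distribution decomposition

Contact distances are analysed cumulatively — the empirical CDF needs
no binning or clustering decisions. Model CDFs are fitted by unweighted
least squares against the midpoint plotting positions (i − 0.5)/n at
the ordered data; midpoint positions avoid the 0/1 endpoints and make
the single-Gaussian fit location-equivariant.

The single-Gaussian model Φ((x−μ)/σ) captures the broad population of
nonspecific van der Waals contacts. The bi-normal mixture adds a narrow
component; it is fitted by multistart bounded least squares (narrow
component initialised at the lower data decile; additional seeded random
starts; σ bounded below at 0.005 Å so the narrow component cannot
collapse onto a point mass; weight parametrised by a logistic transform).
One start embeds the converged single-Gaussian solution with w₂ ≈ 0, so
the mixture residual sum of squares is never worse than the nested
single-Gaussian fit; ties are broken toward lower rss, then lower w₂.
Components are reported in canonical order, σ₂ ≤ σ₁.

The mixture weight w₂ is left free (fixing the proportion would require
knowledge the survey is meant to produce). Angles are summarised
(mean ± sd per acceptor residue or class) but not fitted — the
angle–distance relation is treated as descriptive.

### Anderson–Darling test

Normality of the distance sample (truncated at 3.7 Å by default, since
beyond-cutoff pairs are systematically overrepresented) is tested with
the Anderson–Darling statistic for the case where both μ and σ are
estimated, using the small-sample adjustment A²* = A²(1 + 0.75/n +
2.25/n²) and Stephens' critical values (0.752 at α = 0.05). The raw
statistic agrees with `scipy.stats.anderson` to numerical precision;
the test requires n ≥ 8. Type-I calibration at the nominal α is
verified by simulation in the test suite.

## Dose-response IC50

Scintillation counts follow the one-site competitive inhibition model

    c(x) = C_min + (C_max − C_min) / (1 + (x/IC50)^h)

with Hill slope h fixed at 1 by default (a free slope is available but
off by default; the compound series binds one site). At x = 0 the model
returns C_max, at x = IC50 the midpoint of the asymptotes.

Counts in this kind of assay carry multiplicative error — a roughly
constant coefficient of variation rather than constant absolute noise —
so the default loss divides each residual by the model value
(`loss="relative"`); this is ordinary weighted least squares with the
statistically matched weights, and under simulated 5% CV noise it is
what makes IC50 recovery tight (≥ 95% of estimates within 15% of truth
at the 7-point grid in triplicate). Plain unweighted least squares is
available as `loss="absolute"`.

The optimiser is global: by default a deterministic multistart of
bounded least-squares refinements over a log-spaced grid of IC50
initialisations plus a few seeded jittered restarts (the 3-parameter
hyperbola has a well-behaved loss, unimodal in log IC50 on model data);
`method="anneal"` substitutes simulated annealing with a geometric-like
cooling schedule before the local refinement. IC50 is parametrised
internally as log10(IC50) with bounds two decades beyond the tested
concentration range; the standard error of IC50 comes from the
Gauss-Newton covariance at the optimum via the delta method. The fit
is scale-invariant in counts: rescaling all counts by k rescales
C_max, C_min by k and the reported rss by k², leaving IC50 unchanged.

Design requirements: at least 4 distinct nonzero concentrations
spanning at least one decade.

## QSAR

Activities span 0.27 µM to the > 2000 µM bound of the inactive parent
compound, so the response is always log10(IC50/µM). The parent's
censored activity is handled by explicit policy: `censor="exclude"`
drops it (n = 9), `censor="bound"` keeps it at 2000 µM (n = 10); the
two prespecified regressions use exclude for the (V_mol, pKa) model's
9-point variant and bound for the 10-point fits, matching their quoted
degrees of freedom F(2,7)/F(2,6) and F(1,8).

Models are ordinary least squares (via statsmodels) reporting R², the
overall F statistic and its degrees of freedom; the identity
F = (R²/k)/((1−R²)/(n−k−1)) holds to numerical precision and is
asserted in tests. The energy model uses the unweighted sum
ΔG_diss + ΔG_solv(anion) as a single regressor (its quoted F(1,8)
implies one predictor). No multiple-testing correction is applied —
two prespecified models. Descriptor screening is a PCA of the
correlation matrix of the standardized descriptor block (constant
columns are an error); loadings are orthonormal eigenvectors ordered by
explained variance. Binding-energy correlation fits log10(IC50) against
the docking ΔG_bind column (neutral-form energies by default, which
best track the measured series) and reports per-compound residuals both
in log units and divided by the fitted slope, i.e. in kcal/mol
equivalents — a compound more active than its binding energy predicts
appears as binding underestimated by that amount. Leave-one-out
diagnostics report Q² = 1 − PRESS/TSS and deleted residuals, the
standard robustness check for 9-10-point descriptor models.

## Synthetic-data generators

Every generator is a pure function of its arguments; the same seed
reproduces outputs bit-identically, and the manifest records the truth
used.

* **Dose-response**: counts = model × (1 + ε), ε ~ N(0, cv²), floored
  at zero, on a 7-point geometric grid from 0.016 to 250 µM, cv = 5%,
  three replicates per concentration (the assay protocol's minimum
  number of independent experiments). A Poisson option exists; at count
  levels in the hundreds the two are practically indistinguishable and
  CV is easier to state.
* **Contact distances**: i.i.d. draws (by rejection) from the
  two-component normal mixture truncated to a window; defaults
  μ₁ = 3.34, σ₁ = 0.28, μ₂ = 2.90, σ₂ = 0.04, w₂ = 0.15 on [2.5, 4.0] Å
  — the survey conditions the distance statistics are designed for.
* **Synthetic complexes**: minimal glycine/Ser/Lys/Cys/Phe/water
  fragments plus a halogenated hetero ligand, positioned so each
  requested contact has exactly the requested (d, C–X…Acc, X…Acc–C)
  geometry; decoy waters sit beyond 4.5 Å of every halogen. Coordinates
  are quantized to the PDB format's 3-decimal precision *before* the
  achieved geometry is measured, and the manifest records both the
  requested and the achieved values (they differ by ≲ 2×10⁻³ Å /
  ≲ 0.1°); the scanner must reproduce the achieved values exactly,
  which makes the generator a constructive oracle for the scan.
* **Descriptor tables**: descriptors uniform over the ranges of the
  measured series (V_mol 127.1–213.0 Å³, pKa 4.78–8.56), response
  linear with known coefficients plus Gaussian noise.

What the generators do **not** emulate: crystallographic disorder
(B-factors, altloc populations, occupancy), correlated contacts within
one binding pocket, real ring geometry of fused heterocycles, assay
drift or outliers, and descriptor collinearity structure beyond what
uniform sampling produces. Passing tests on synthetic data therefore
demonstrate correctness of the algorithms under the stated noise
models, not robustness to every pathology of real crystal structures
or assays.

A constructed stand-in complex (`build_synthetic_ck2_complex`) plants
the published spot-check geometry of the kinase–tetrabromobenzotriazole
complex — a 2.99 Å Br…Nε arginine contact and triazole N–N bonds of
1.242/1.419 Å — so the parse/scan/measure path can be exercised end to
end without structure retrieval. It is a miniature built from scratch,
clearly labelled synthetic; analyses of real deposited structures
require user-supplied PDB files (the CLI `scan` takes any file, and
surveys over curated structure sets are run by scanning each file and
concatenating contact tables).

## Problem sizes

Defaults used by the test suite and the acceptance script, chosen to
give stable statistics at interactive runtimes: survey decomposition at
n = 2000 distances; mixture-recovery check at n = 500 with 50 bootstrap
resamples; IC50 recovery over 200 simulated triplicate assays;
Anderson–Darling calibration over 1000 replicates of n = 100;
scanner round-trip over 50 random complexes with 1–3 planted contacts.

## Known limitations

* Bond inference is purely distance-based (X–C ≤ 2.1 Å, anchor ≤ 1.8 Å);
  ligands with unusual bond lengths or missing atoms may mis-anchor.
* The π-acceptor definition (ring centroid, no angle) is a convention;
  face-on versus edge-on approach is not distinguished.
* The censored parent compound enters 10-point fits at its activity
  bound; the true value could be anywhere above it, and the 10-point
  R²/F inherit that convention.
* The Anderson–Darling decision uses fixed critical values at five α
  levels rather than interpolated p-values.
* With n = 500 survey-scale samples the narrow mixture component's σ is
  estimated with limited precision (bootstrap spread ≈ 0.01 Å at a true
  0.04 Å); survey-scale inference on real data should report bootstrap
  intervals, not point estimates.
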