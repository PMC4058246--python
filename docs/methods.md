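# Methods

This note documents the models, conventions and numerical choices behind
each module, what the synthetic generators do and do not emulate, and the
known limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Molecular graphs

Structures enter as SMILES or SDF and are parsed with RDKit; everything
downstream operates on the package's own hydrogen-suppressed
`MolecularGraph` (element, formal charge, attached-H count, aromatic flag,
principal quantum number per atom; order + aromatic flag per bond).
Choices:

* **Aromaticity** follows RDKit's default perception (Hückel-style on
  rings), which yields the aromatic atom-type codes (`aaN`, `aaNH`, `aaCH`)
  the descriptor names presuppose without a separate kekulization engine.
* **Hydrogens** are counts on heavy atoms, except in the composition
  descriptors (IC/BIC/IAC), which expand them to nodes on the fly.
* **Charges**: common zwitterions and simple ions are neutralized at parse
  time (protonated amines lose a proton, deprotonated O/N/S gain one).
  Ionization-state modeling is out of scope; descriptors describe the
  neutral species. δᵥ is charge-adjusted for any charge that survives.
* **Stereochemistry** is parsed and discarded — every descriptor here is
  2-D topological.
* Multi-fragment inputs (salts) are rejected rather than silently split.

## Descriptors and their convention knobs

The E-state uses Iᵢ = ((2/Lᵢ)²·δᵥᵢ + 1)/δᵢ with δᵥ = valence electrons −
attached H (charge-adjusted), and the perturbation ΔIᵢ = Σⱼ (Iᵢ−Iⱼ)/(dᵢⱼ+1)²
with d in bond counts — the dominant published convention for the distance
damping (`estate_distance_offset = 1`). CHI_3_P sums (δₐδᵦδ꜀δ𝒹)^(−1/2) over
all 3-bond simple paths with plain heavy-atom degrees, each undirected path
counted once.

Vendor descriptor catalogues disagree on the information-content and
Balaban variants, so those are explicit knobs on `DescriptorConventions`:

| knob | default (literature) | vendor-emulation preset |
|---|---|---|
| `ic_graph` | hydrogen-expanded | heavy atoms only |
| `ic_order` (neighborhood radius) | 1 | 2 |
| `bic_denominator` | log₂(bond count) | log₂(atom count) |
| `jy_weight` | Sanderson 1/(yᵢyⱼ) per bond step | unit (classic J) |

IC partitions the chosen atom set by iterated neighborhood refinement
(order 1 ≡ element + degree + neighbor-element multiset) and takes the
Shannon entropy in bits; BIC normalizes it by the chosen log₂ count
(zero-guarded below two). IAC_Mean is always the entropy of the elemental
composition including hydrogens. JY weights each bond step of the distance
matrix by the product of Sanderson electronegativities relative to carbon
(table shipped in `descriptors.py`), so all-carbon molecules reduce to the
classic Balaban J under either setting.

**Calibration of the vendor-emulation preset.** The frozen published model
was trained on descriptors from a proprietary package (undocumented BIC,
IAC_Mean and JY variants). Under the default literature conventions the two
published worked-example predictions (5.89 and 6.31) are not reproduced
(3.86 / 3.98); treating the candidates as physiological zwitterions does
not close the gap either (4.33 / 3.87). The convention knobs above, plus
the E-state damping offset and IC order 0–4, were therefore swept against
the two published predictions; the best joint match —
`DS_EMULATION = (heavy, order 2, atoms, unit)` — reproduces them as
**5.78 / 6.41**, a residual deviation of 0.109 / 0.095 pEC50 units (≈1.9% /
1.5%). No swept combination matches to 2 d.p., so the residual is treated
as irreducible vendor-definition mismatch; the preset is frozen, recorded in
output metadata, and the hand-value/brute-force oracle suite under the
default conventions remains the binding correctness gate for every
descriptor.

Descriptors are carried at full precision; CSV output rounds to 6 decimals.

## Activity models

* **MLR**: ordinary least squares with intercept (rank checked; collinear
  columns named in the error). Diagnostics report both the coefficient of
  determination and the squared Pearson correlation of observed vs
  predicted (the two common "R²" readings), plus leave-one-out q² computed
  from the hat matrix (PRESS) without refitting.
* **SVR**: ε-insensitive support-vector regression through scikit-learn's
  libsvm solver — the same solver family the original workflow used.
  Descriptors are standardized internally; the stored model carries support
  vectors and dual weights so JSON round-trips are prediction-exact. Note
  the ε-tube: on noise-free data the optimum leaves residuals up to ε, so
  agreement with the interpolating fit is O(ε), not machine precision.
* **Bayesian linear regression** stands in for the original, unspecified
  "Bayes network" regressor: Gaussian prior N(0, α⁻¹I) on slopes, flat
  prior on the intercept, noise precision λ; the posterior mean is the
  point prediction. α→0 recovers OLS, α→∞ shrinks to the training mean.
  This is the closest reproducible continuous-outcome Bayes model; it is a
  deliberate, documented substitution.
* pEC50 is taken as log₁₀(1/EC50); prediction intervals use the classical
  MLR t-formula and are labelled as such.

## Genetic descriptor selection

Chromosomes are unique, sorted descriptor-index tuples. Fitness is the OLS
training R² of the selected columns (rank-deficient selections get −inf),
or negated Friedman lack-of-fit LOF = SSE/(n·(1−(c+d·p)/n)²) when size
should be penalized — plain R² never decreases when a column is added, so
the r2 fitness is only meaningful under a length cap (a tested property).
Operators: tournament selection (size 2), single-point crossover on sorted
gene lists with duplicate-free repair, per-gene mutation to a random unused
descriptor, elitism of one. Ties break toward the lexicographically
smallest gene tuple, making runs bit-reproducible per seed. Defaults
(population 60, 100 generations, crossover 0.9, mutation 0.05, max length
6, fixed-length-6 mode available) were chosen to recover planted
six-descriptor models reliably at n ≈ 20–40. Cross-validation is LOO by
default (the original report does not state its scheme).

## Screening funnel

Rule-of-five flags use strict exceedance (exactly 500 g/mol passes); HBD =
N/O bearing ≥1 H, HBA = N+O count; logP is an injected annotation — absent
logP marks the criterion "not evaluated" and passes with a warning rather
than silently failing a compound. The activity gate requires
min(predictions) ≥ threshold; the threshold default is 5.0 pEC50 (10 μM)
since the original "acceptable activity" rule is unstated, and it is
configurable. Dock scores and any externally published predicted-activity
columns are injected inputs (`frozen_table_model` predicts by compound id);
survivors are ranked by dock score descending with ties broken by compound
id. The report keeps one row per library compound, errors included.

## Trajectory statistics

Distances in nm (PDB Å are divided by 10 on read), times in ps, angles in
degrees, masses in Da. Superposition is Kabsch via SVD with the
determinant correction, optionally mass-weighted; RMSD needs ≥3 fit atoms.
RMSF superposes each window frame onto the window-average structure,
refining the average with a second pass (the reference structure choice is
not dictated by the source workflow), then takes √⟨‖xᵢ−⟨xᵢ⟩‖²⟩. H-bond
occupancy is a pure distance criterion between the two named atoms (0.3 nm
default cutoff, no angle term), reported as percent at 2 d.p. GROMOS
clustering iteratively removes the frame with most neighbors within the
RMSD cutoff together with those neighbors; the representative is the
cluster medoid — the member minimizing summed RMSD to co-members — which is
the adopted reading of a "middle RMSD" structure (a median-to-centroid
alternative would be a one-line change; the ambiguity is deliberate and
logged). Torsions use the signed atan2 dihedral in (−180°, 180°] with no
unwrapping; colinear geometries yield NaN with a warning. Moving averages
are centered with edges truncated to available frames (window 21 by
default). Tie-breaks everywhere favor the lowest frame index.

The O(F²) pairwise-RMSD matrix limits clustering to windows of a few
thousand frames; that is ample for the intended representative-structure
use.

## Synthetic data

* **Training tables**: X i.i.d. standard normal (optional equicorrelated
  planted block), y = β₀ + X_planted·β + N(0, σ²). Defaults emulate the
  published training regime: n = 20, the six model descriptors as planted
  columns with the frozen-equation coefficients as β, and σ set so the
  *training* R² centers on 0.85 — `sigma_for_r2` inverts
  E[1−R²_train] ≈ (1−R²_pop)·(n−k−1)/(n−1) before the population-R²
  inversion, since at n = 20, k = 6 the training R² is noticeably inflated
  over the population value. Realized training R² still spreads roughly
  ±0.1 across seeds at this n; tests assert the distribution, not single
  draws.
* **Trajectories**: a uniform random scaffold with per-frame, per-atom
  Gaussian jitter; basin mode adds a fixed large random deformation per
  basin so superposed inter-basin RMSD ≫ intra-basin spread. This captures
  exactly the structure the statistics assume (isotropic fluctuation about
  references) and none of the physics — no bonded constraints, no
  anisotropy, no diffusive drift — so passing tests certify the estimators,
  not force-field realism.
* **H-bond series**: a two-state Markov (telegraph) process with stationary
  bound fraction p and mean bound dwell 50 frames, matching the
  autocorrelated switching of real contact series rather than i.i.d.
  flips. The autocorrelation inflates the sampling error of the occupancy
  estimate well beyond the binomial bound (≈√(p(1−p)·2·dwell/F)), which is
  why the occupancy checks run at fixed seeds and 10⁴ frames.

All generators are pure functions of (spec, seed); NumPy `default_rng`
throughout.

## Fixtures

5-hydroxy-L-tryptophan (C₁₁H₁₂N₂O₃) and abrine (N-methyl-L-tryptophan,
C₁₂H₁₄N₂O₂) are canonical structures. The saussureamine A–C and T2384
entries are clearly-labelled best-effort reconstructions (no authoritative
machine-readable structures are available): the saussureamines as
dehydrocostus-lactone amino-acid Michael adducts, T2384 as a
sulfonamide-bearing oxazole acid. Nothing quantitative depends on these
four beyond rule-of-five passage and their injected dock scores.

## Known limitations

* The published training R² values (0.8442/0.8536/0.7612) are not
  reproducible on principle — the 20-compound training set was never
  printed; the synthetic generator emulates its regime instead.
* Dock scores are never computed; docking, pose generation, ADMET models,
  secondary-structure assignment and MD propagation are explicitly out of
  scope.
* The vendor-emulation descriptor preset carries the documented ≈0.1
  log-unit residual against the two published predictions; downstream users
  comparing against vendor descriptor values should expect variant-level
  differences in BIC/IAC/JY.
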