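# Methods

## Scope and units

`acetrace` analyses stable-isotope acetate tracing in adherent cell
culture: cells in a known medium volume, biomass tracked as packed cell
volume (PCV), medium and hydrolysate acetate measured by GC-MS selected
ion monitoring, and fatty-acid labeling measured as mass isotopomer
distributions (MIDs). Throughout: time in hours, concentrations in μM,
PCV in μL/well, medium volume in mL, fluxes in mmol/hr/L cell volume
(release-positive net exchange). Flux normalization to cell volume rather
than cell number makes conditions with different cell sizes comparable and
is what the area-under-the-growth-curve denominator T (L_cell·hr/L_medium)
delivers.

## Natural-abundance correction

Raw MIDs include mass shifts from naturally occurring heavy isotopes of
every atom in the derivatized ion (¹³C 1.07%, ²H 0.0115%, ¹⁷O 0.038%,
¹⁸O 0.205%). Because fatty-acid methyl esters carry many H and O atoms, a
carbon-only correction biases high-mass isotopomers, so the correction
matrix convolves per-atom distributions for all elements. Column j of the
matrix is the natural mass-shift distribution of a molecule with j
tracer-labeled carbons (the labeled positions pinned at +1 Da, all other
atoms — including unlabeled tracer-position carbons — drawing from their
natural distributions), truncated at the measured window M+0..M+n.
Correction solves the resulting lower-triangular system directly; the
condition number is checked (default limit 1e8) and failure is loud.
Small negative corrected fractions are clipped to zero and the MID
renormalized, with a warning once clipped mass exceeds 1e-3 — clipping is
a routine noise artifact but must stay visible.

## Internal-standard quantification

²H₃-acetate added before derivatization (default 40 μL of 1 mM into
200 μL, i.e. an effective 200 μM) quantifies both acetate species within
one run: c₁₂ = (I₆₁/I₆₄)·C_IS and c₁₃ = (I₆₃/I₆₄)·C_IS. The three esters
differ only isotopically, so equal response factors are assumed
(single-point isotope dilution, no calibration curve). M+2 natural
cross-talk of the light ester into m/z 63 is < 0.1% for a two-carbon
fragment and is neglected. A zero internal-standard channel raises an
error rather than yielding silent zeros. Medium evaporation and blank
drift are not modeled: cell-free medium acetate is stable over the
experiment's duration.

## Exchange fluxes

Net exchange e = ΔC_total/T. The deconvolution into gross release r and
uptake u uses the two balance equations e = r − u and xe = a·r − b·u and
is solved from Δ-quantities directly so e = 0 poses no difficulty. Design
choices:

* **Average medium fraction b.** Uptake samples the medium composition in
  proportion to instantaneous cell volume, so with ≥3 time points b is the
  cell-volume-weighted trapezoidal time average of c₁₂/c_total; with only
  two points it falls back to the endpoint mean (`b_mode` selects either).
  With realistic gross exchange (~one medium-pool turnover per day) the
  medium composition drifts substantially within a sampling window, and
  the endpoint mean then biases r and u by >10%, while the weighted
  average recovers simulated fluxes to <1% at zero noise.
* **The a-scan.** The intracellular free acetate pool is too small to
  quantify, so a is scanned. Endogenous acetate production (deacetylation,
  glucose/glutamine-derived) is unlabeled, and influx from the medium has
  unlabeled fraction b, so a cannot fall below b: the default grid is 101
  uniform points on [b, 1] (configurable). Grid points with |a − b| below
  1e-6 are excluded as singular; points yielding negative r or u are
  excluded as unphysical rather than clipped, and an empty retained range
  is a diagnostic error. The reported r_q05/u_q05 are 5% quantiles over
  all retained solutions — one-sided lower bounds by construction.
* **Replicates.** With ≥3 wells, a seeded nonparametric bootstrap
  (default 1000 draws) over wells is pooled with the a-scan; e's median
  and 95% CI come from the bootstrap alone since e does not depend on a.
* **Release/consumption ratio.** Δc₁₂/(−Δc₁₃) over the series span is
  cell-number independent and defined only under net tracer consumption.

## Isotopomer spectral analysis

The two-pool precursor model treats each acetyl unit as fully labeled
(M+2, probability D) or unlabeled — M+1 units are out of model, and
odd-shift mass above a threshold (default 2%) after correction triggers a
warning while the fit uses even shifts only. The fit minimizes the sum of
squared residuals over even shifts on a (D, g) grid of step 0.005,
followed by one local refinement pass at 1/50 of the step; ties break
toward smaller g then smaller D, so an all-M+0 input returns exactly
(0, 0). Grid-plus-refinement was chosen over gradient descent for
determinism and bounded runtime; the refinement makes the effective
resolution ~1e-4, well below measurement noise. g and D are always fitted
jointly: at long labeling times g→1 and D is identified by the even-shift
shape alone, but the joint fit stays correct when turnover is incomplete.
Fatty acids other than palmitate are supported through `n_units`
(chain length / 2).

For time courses, a single shared D with one g per time point is fitted:
for fixed D the optimal g of each sample has a closed form (a clipped
projection), so the joint search remains a 1-D scan over D.

## Kinetic flux profiling

At constant pool size P the label balance dg/dt = (J_syn/P)(1 − g) gives
g(t) = 1 − exp(−k·t); nonlinear least squares on the g(t) series yields k,
J_syn = k·P and the acetyl demand 8·J_syn. The constant-pool first-order
form is the canonical kinetic-flux-profiling model; growth dilution is
folded into k and the model function is pluggable for other assumptions.
P (mmol palmitate/L cell volume, default 25 in the simulator) must be
supplied — absolute palmitate quantification is out of scope. Fitting on
g rather than raw intensities decouples MS response from kinetics. The
demand/uptake comparison is only defined under net uptake; net-release
conditions raise an explicit error.

## Histone-bound acetate

Histones are hydrolyzed in bulk, so the measurement is the aggregate
histone-bound acetate pool (no per-site resolution); the hydrolysate runs
through the same SIM quantification with matrix effects assumed equal to
medium (declared assumption). Percent labeling 100·c₁₃/(c₁₂+c₁₃) is
scale-invariant in intensities. The lipogenic/histone contrast ratio
operationalizes the nuclear-vs-cytosolic acetyl-CoA comparison; a ratio
well above 1 for the acetate tracer indicates limited equilibration
between the pools.

## Synthetic data

The simulator generates exactly the statistical structure the analysis
assumes, plus multiplicative lognormal intensity noise (mean-1, default
CV 2%) on every channel:

* growth: pcv(t) = pcv0·2^(t/doubling_time), default 1 μL/well seeding in
  3 mL medium, doubling 40 h (normoxia) to 60 h (hypoxia/low serum);
* medium acetate: fixed-step RK4 (0.1 h) on
  d(c_total)/dt·V_med = (r − u)·V_cell(t),
  d(c₁₂)/dt·V_med = (a·r − b(t)·u)·V_cell(t) with b(t) = c₁₂/c_total;
  uptake tapers linearly below 5 μM total acetate (configurable) so pools
  stay non-negative when the tracer is nearly exhausted;
* palmitate MIDs: forward binomial model at g(t) = 1 − exp(−k·t),
  convolved with the natural-abundance matrix of the methyl ester
  C₁₇H₃₄O₂;
* histone hydrolysate: intensities inverted from the preset per-tracer
  percent at a nominal 50 μM hydrolysate concentration.

Condition presets are anchored to the study design: 90 μM U-¹³C-acetate
over ~15 μM residual unlabeled acetate; MDA-MB-468 with balanced uptake
and release of 3.5 mmol/hr/L cell and intracellular unlabeled fraction
a = 0.9; hypoxia raising lipogenic enrichment to D = 0.30; BT-474 low
serum with net uptake 8 mmol/hr/L cell and negligible release (the
condition with the highest ACSS2 expression retains endogenous acetate
almost completely, which is also the only configuration consistent with a
30% net-uptake reduction when synthetase silencing scales uptake by 0.7);
the BT-474 presets use 500 μM tracer so the medium pool is non-limiting
over their 48 h flux window; the hypoxia/low-serum demand preset pairs
net uptake 4 with acetyl demand 10 (k = 0.05/hr on a 25 mmol/L-cell
pool), and fatty-acid supplementation halves k; histone panels put the
acetate contribution at 8% (normoxia) and 15% (hypoxia/low serum).
Exchange windows are 24 h (48 h for BT-474) sampled every 4–8 h — short
enough that the medium composition stays quasi-stationary, which is what
makes the a-scan bounds tight; KFP time courses sample 0–48 h.

What the simulator does **not** emulate: chromatographic artifacts,
derivatization yield variation, medium evaporation, lag or contact
inhibition in growth, M+1 acetyl units from exchange fluxes, pool-size
growth during the KFP window, and correlated (rather than independent
per-channel) measurement error. Passing recovery tests therefore
demonstrates correctness of the estimators under the model's own
assumptions, not robustness to every real-data pathology.

## Numerical choices and degenerate inputs

RK4 at 0.1 h steps keeps the integrator error orders of magnitude below
the 2% recovery tolerances; trapezoidal growth integration at 4-h
sampling contributes <0.1% error for exponential growth. Quantiles use
numpy's default linear interpolation. Zero-length integration intervals
return 0; zero internal standard, singular (a ≈ b) balances, empty
retained a-ranges, sub-2-point rate fits and net-release demand ratios
all raise typed errors rather than returning sentinel values.

## Known limitations

* r and u are bounded, not point-identified; only e is.
* D from a single tracer does not separate synthetase isoform
  contributions to the lipogenic pool.
* The KFP model ignores pool expansion during rapid growth; k then
  absorbs dilution and J_syn is condition-comparable rather than
  absolute.
* Equal-response-factor quantification holds for isotopologues of one
  derivative only; it would not extend to chemically distinct standards.
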