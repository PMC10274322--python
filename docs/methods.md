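# Methods

## Speciation model

Urine is treated as an aqueous electrolyte at fixed temperature (38 °C,
canine/feline body temperature) whose proton activity is known exactly from
the glass-electrode pH. The solver therefore clamps a_H = 10^(−pH) and
writes no proton mass balance — the EQUIL-family design. For every other
component j (Ca, Mg, Na, K, NH₄, Cl, SO₄, PO₄, Ox, Cit, and optionally Ur,
PyroP, CO₃) with analytical total T_j:

* mass balance: T_j = [j] + Σ_k n_kj [C_k]
* mass action per complex k: [C_k] = β_k Π_j a_j^{n_kj} / γ_k on the molar
  activity scale, a_j = γ_j [j]

Hydroxide and hydroxo complexes are encoded with negative proton
stoichiometry: the registry entry `OH = {H: −1}` with log β = −pKw *is* the
water ion product, and e.g. `MgOH = {Mg: 1, H: −1}` folds the hydrolysis
constant and pKw together. This keeps the model a pure product form with
one special species (H) and no separate hydroxide machinery.

Ammonium is the component (it is what the indophenol assay measures);
ammonia loss at high pH appears as the complex `NH3 = {NH4: 1, H: −1}`.

### Activity model

Davies equation, log₁₀ γ = −A z² (√I/(1+√I) − b·I) with b = 0.3 and
A = 0.5221 (the Debye–Hückel limiting slope at 38 °C); neutral species get
γ = 1 (the Davies form is not useful at z = 0, and salting-out corrections
are beyond scope). An `ideal` switch (γ ≡ 1) exists for testing and for
constructing exact saturation fixtures. Typical urine has I ≈ 0.15–0.3
mol/L, at the edge of the Davies validity range — a known limitation shared
by the programs this package emulates; per-ion extended Debye–Hückel size
parameters are a possible registry extension.

### Numerics

Outer fixed-point iteration on ionic strength/activity coefficients around
an inner damped Newton iteration on x = ln[j]:

* residual F_j = [j] + Σ_k n_kj[C_k] − T_j, scaled by max(T_j, ε)
* Jacobian ∂F_j/∂x_i = δ_ji[j] + Σ_k n_kj n_ki [C_k] (symmetric, cheap)
* log-space steps keep every concentration positive by construction;
  steps are capped at 2 natural-log units per iteration
* inner convergence: max |step| < tol_rel (default 1e−9) AND every relative
  residual ≤ tol_mb (default 1e−8); outer convergence: relative change in
  I below 1e−12 (skipped under the ideal model, where γ never changes)
* initial guess free = total (exact in the dilute limit); iteration caps
  200 inner / 60 outer; non-convergence raises in strict mode, otherwise
  returns a result flagged `converged=False`

The contract is scheme-independent: tests cross-check the solver against a
MINPACK Powell-hybrid root solve of the same equations in plain
concentration space (an entirely separate code path) to 1e−6 relative on
randomized systems; observed agreement is ~1e−13.

Degenerate inputs are legal: a zero total removes that component (and every
complex involving it) from the system; an all-zero panel returns the water
equilibrium only. Analytes with zero totals that the loaded registry does
not track are ignored rather than rejected, so reduced toy registries work
with full panels.

## The constants registry

No blessed coefficient table exists in the open literature for the
historical RSS binaries; the shipped default registry is a reconstruction
of the classical EQUIL lineage from critical-stability-constant
compilations (NIST SRD 46 / Smith & Martell and the urolithiasis
literature), with each entry's source noted in its `provenance` field.
Correctness of the package is defined against whatever registry is loaded.
Key choices:

* log-scale constants only (log β, log Ksp) — raw K values under- and
  overflow and invite transcription errors
* struvite is the hexahydrate MgNH₄PO₄·6H₂O; water of crystallization has
  activity 1 and does not enter the IAP
* caox Ksp 10^−8.65 (whewellite, ~38 °C); struvite Ksp 10^−13.26 (the
  classical value — newer determinations are higher, which is precisely the
  kind of coefficient disagreement the compare module quantifies)
* a machine-readable JSON schema for the format ships in
  `src/urisat/data/constants.schema.json`; the loader enforces the same
  constraints natively (cross-references, per-complex charge balance,
  lattice electroneutrality)

`perturb_constants` produces a derived registry with scaled salt Ksp values
and/or shifted log β values — the mechanism for emulating a second program
with "slightly different coefficients". Scaling a salt's Ksp by k is exactly
equivalent to dividing that salt's RSS by k on every sample (speciation is
untouched), which is why between-program scatterplots from coefficient
disagreement are straight lines through the origin.

## RSS definition

RSS = IAP / Ksp, the raw activity-product ratio. Some programs report the
per-ion form (IAP/Ksp)^(1/n) (n = ions per formula unit, 2 for CaOx, 3 for
struvite); that alone produces slope-like disparities between programs, so
it is exposed separately as `rss_nth_root` and never silently mixed in.
RSS > 1 is reported as supersaturation, never as a clinical stone-risk
verdict: stone formation additionally depends on nucleation and the surface
energy of the solid phases, which no thermodynamic index captures.

## Agreement statistics

Four assessments on paired series (x = New program, y = Control program;
every difference is Control − New, stated in each output):

* paired t: d̄, se = sd(d)/√n (sample sd), t = d̄/se, two-sided p on n−1 df;
  zero-variance differences yield t = p = undefined rather than a fabricated
  p-value
* Lin's CCC with population (1/n) moments per the original estimator
  (`ddof=1` variant behind a flag); CCC ≤ |Pearson r| always
* OLS of Control on New with slope CI = slope ± t(0.975, n−2)·se; a CI
  containing 1 is read as agreement on scale; r² = share of Control
  variance explained by New
* Bland–Altman: differences vs pair means with limits at mean ± 2·sd and
  ± 3·sd of the differences (literal 2 and 3, not 1.96)

Pairs with a missing member are dropped and counted (`n_dropped`), never
imputed.

## Synthetic cohorts

The generator emulates 24-h urine panels from healthy adult dogs and cats:
log-normal analyte marginals (urine concentrations are positive and
right-skewed), truncated-normal pH, optional Gaussian-copula rank
correlation (off by default — no published covariance structure exists to
calibrate it against). Preset medians and geometric SDs come from published
companion-animal urine reference intervals; they were chosen once, for
realism, and are calibrated only qualitatively: the resulting RSS
distributions are right-skewed with CaOx CV near 80–110 % and struvite CV
far above it (≈180–300 %), the order of magnitude real cohorts show. The
presets do not reproduce any specific study population, and passing tests
on synthetic cohorts demonstrates solver and statistics correctness — not
that the presets match any laboratory's animals. Features of real data not
emulated: analyte cross-correlations (diet drives Na/Cl/K together),
day-to-day within-animal variation, assay noise, and censoring at detection
limits.

Problem sizes used by the acceptance script — 380 canine and 494 feline
panels, 1000 panels for conservation checks, 100 randomized systems for the
oracle comparison, 10⁴ draws for the Bland–Altman coverage — match the
scale of the motivating study design and complete in seconds.

## Known limitations

* Davies at urine ionic strengths is an approximation; no ion-size
  parameters in v1.
* Constants carry no temperature dependence (no van't Hoff correction);
  the registry is defined at 38 °C only.
* Fixed-pH means titration/charge-balance questions are out of scope.
* Only caox and struvite are certified; other salts in a registry are
  evaluated on request but not covered by the test battery.
* The solver reports supersaturation; it never removes solid phase
  (no precipitation mass transfer, no kinetics).
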