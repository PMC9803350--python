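# Methods

## Scope and model

`skcam` quantifies how the Ca²⁺-gated SK2 channel's calmodulin-binding
domain (the peptide **SKp**, residues 396–487 of rat KCa2.2, 11.1 kDa)
associates with calmodulin (**CaM**) constructs. The central object is a
mass-action equilibrium over two monomers, peptide P and CaM construct C,
and a set of complexes PᵢCⱼ:

    i·P + j·C  ⇌  PᵢCⱼ,      K_A(i,j) = [PᵢCⱼ] / ([P]ᵢ [C]ʲ)

with K_A referenced to 1 M and reported as log₁₀ (units M^(1−i−j)). The
stoichiometries of interest carry field names: P-C (1/1), P-C-P
(2 SKp/1 CaM), C-P-C (1 SKp/2 CaM) and 2×P-C (2/2). Composition-gradient
multi-angle light scattering (CG-MALS) observes, at each mixing ratio, the
weight-average molar mass over *all* solution species,

    M_w = Σₖ nₖ Mₖ² / Σₖ nₖ Mₖ ,

which is what constrains the K_A values: at peptide excess a P-C-P
shoulder raises M_w, at CaM excess a C-P-C shoulder does, and with all
three complexes present the curve takes the characteristic two-peaked "M"
shape whose features localize the constants. A 1:1-only system instead
gives a single triangular apex bounded by the 1/1 complex mass.

Assumptions: small particles (form factor P(θ) = 1), negligible virial
corrections, ideal mass action, and a single refractive-index increment
for all species. Ca²⁺ is not modelled at the site level; it enters only
through which fitted constant set (trace-Ca²⁺/EGTA vs saturating Ca²⁺)
parameterizes the model.

## Speciation solver

`solve_speciation` finds free monomer concentrations satisfying both
conservation equations

    [P] + Σ i·K_ij [P]ᵢ[C]ʲ = P_tot ,   [C] + Σ j·K_ij [P]ᵢ[C]ʲ = C_tot .

Because the constants span more than twenty decades, the solver works in
log space (variables ln[P], ln[C]) with a damped Newton iteration
(initial guess free = totals; steps halved until the residual norm
decreases; trust region of 50 log units; iteration cap 200; default
relative tolerance 1e−9). Positivity is guaranteed by construction.

Two numerical points matter:

* **Cancellation-free Newton algebra.** When one complex dominates, the
  2×2 Jacobian is nearly rank one and the textbook determinant
  `(p+T)(c+T) − T²` loses all significant digits (T is the dominant-term
  scale, up to ~10³⁰ above the totals during early iterations). The
  determinant and step numerators are therefore evaluated in expanded
  pairwise form — e.g. det = pc + p·Σj²Tₖ + c·Σi²Tₖ + Σ_{a<b} TₐT_b
  (iₐj_b − i_bjₐ)² — in which every term is non-negative and the
  cross-stoichiometry factors vanish identically for a single complex.
* **Fallback.** If Newton stalls, a nested bisection on the two
  conservation equations (inner solve for ln[P] given ln[C], outer on
  ln[C]) finishes the job; its bracket is widened by the largest ln K so
  strong binding can always be driven under the totals. Non-convergence
  after both raises with the residuals attached.

Degenerate axes (one or both totals zero) are solved directly; a
peptide-only composition returns the peptide monomer mass for any model.
The solver was validated against the closed-form quadratic for
P + C ⇌ PC over wide K_A sweeps (agreement ≤ 1e−10 relative on free
concentrations) and holds conservation to 1e−9 relative over randomized
models spanning stoichiometries up to (3,1) and constants up to 10²⁴.

## Light-scattering constants

The optical prefactor is evaluated exactly as the instrument convention
used in this study writes it, K* = 4π²(dn/dc)² n₀² / (N_A λ₀²), in CGS
units (dn/dc in ml/g, λ₀ in cm; defaults dn/dc = 0.186, n₀ = 1.33,
λ₀ = 660 nm). Readers used to the Rayleigh–Zimm constant will expect λ₀⁴
in the denominator; since K* cancels identically in the simulate → invert
round trip (`mw_from_rayleigh(excess_rayleigh(s), w_tot) = M_w(s)`), every
mass result in the package is independent of this convention, and the
function documents it rather than silently switching.

## Gradient design and fitting

The cross-over experiment is modelled as a linear series of volume
fractions f of the peptide stock mixed with (1−f) of the CaM stock, with
the published working stocks 0.096 mg/ml SKp and 0.09 mg/ml CaM. The real
instrument's injection series is not published, so the default grid —
41 steps, f ∈ [0.05, 0.95] — was chosen once as a realistic design that
spans CaM:SKp molar ratios ≈ 0.07–12, covering peptide excess, the
equimolar dip and CaM excess. Absolute interior M_w values depend on this
choice; the recovered constants in the noiseless round trips do not.

`fit_association_constants` minimizes the unweighted sum of squared M_w
residuals over steps and replicates by Levenberg–Marquardt (lmfit/MINPACK
`leastsq`), with log₁₀ K_A as parameters. Optional 1/SEM² weighting is
available but off by default since the original analysis does not state a
weighting. Parameters can be fixed, given starting values (default 6.0)
and box bounds (default [−5, 40], the physically meaningful range — the
box exists to keep LM exploration out of regions where the forward model
saturates). A parameter whose error estimate is unavailable (singular
Jacobian) is flagged, never silently accepted.

**Detection limits.** For a pure bimolecular interaction at these
concentrations the data stop constraining K_A above roughly log K_A ≈ 7:
every stronger constant gives an indistinguishable fully-bound curve.
`detection_limit_scan` profiles the RSS over a grid of one parameter
(re-minimizing the rest) and flags the parameter *unconstrained* when the
profile stays within a measurement-resolution threshold of its minimum
over ≥ 2 log₁₀ units. The threshold is the RSS a 2% relative error per
observation would produce (the proportional-noise floor assumed for the
instrument); it scales with the data, not with the fit.

**Model comparison.** `compare_models` fits each candidate stoichiometry
set and selects the smallest set whose RSS is within a factor 1.05 of the
global best (plus a sub-resolution absolute floor so near-zero noiseless
RSS values compare sanely); ties go to fewer parameters. This mirrors a
minimum-variables parsimony argument rather than a formal information
criterion, which the source analysis does not use. Candidate fits without
user-supplied starts use a deterministic multi-start ladder: per-contact
scale s ∈ {4, 6, 8, 10, 12} with each complex started at s·(i+j−1),
reflecting the rough additivity of binding free energies per monomer
contact — single uniform starts leave LM stranded in local minima for the
three-complex "M" data.

**Trial aggregation.** Across independent experiment fits, each constant
is summarized as mean, standard error of the mean (sample SD/√n), and n,
formatted "mean (se)n". The SEM is across-trial by design; the LM
covariance errors are kept as per-fit diagnostics only.

## Emission spectra

Spectra live on the 315–400 nm integer grid (1-nm steps, excitation
265 nm). Reduction: pointwise buffer subtraction (negatives kept and
flagged, never clipped), replicate averaging with per-wavelength SEM
(single replicate → SEM unavailable, not zero), binomial smoothing
(repeated (1,2,1)/4 convolution with reflection padding; variance grows
linearly with passes; linear trends are preserved at interior points),
and peak localization by argmax on the smoothed spectrum at integer-nm
resolution (no sub-nm interpolation; ties take the smaller wavelength;
edge maxima are flagged). The number of smoothing passes is an explicit
required parameter — the original pass count is not recorded anywhere.

Pairwise comparison reports the peak shift Δλ and the amplitude change
(A_s/A_r − 1)·100, so "230% greater" means a 3.3× ratio. The alternative
reading (A_s/A_r = 230%, i.e. 2.3×) is computable from the same numbers;
the literal reading of "greater" is the default and the choice is
deliberate, not load-bearing for any fit.

## Patch-current recovery

Records are 3-s samples of the −60 mV step mean with ordered solution
epochs: EGTA (nominally Ca²⁺-free), 10 µM free Ca²⁺, and Ca²⁺ plus an
applied CaM construct. Leak is the mean of the last k samples of each
EGTA epoch averaged across epochs (SK current is shut without Ca²⁺);
k = 5 (15 s) is a configuration parameter since the averaging window used
originally is unstated. Optional drift correction fits an ordinary
least-squares line over designated Ca²⁺ epochs and subtracts it
(anchored at the window start); correcting twice yields slope ≈ 0.

With leak-subtracted steady currents I_pre (basal Ca²⁺), I_R1 (end of the
non-WT application), I_post (washout before WT) and I_final (end of the
WT application), total recovery is Δ = I_final − I_pre and

    fraction_nonwt = (I_R1 − I_pre)/Δ
    fraction_drift = (I_post − I_R1)/Δ
    fraction_wt    = (I_final − I_post)/Δ

summing to 1 identically. This three-part split — construct effect,
washout drift, WT completion — is one consistent reading of the
stacked-bar presentation of such experiments; the exact formula used
originally is not printed, so published per-construct summary values are
shipped as comparison fixtures, not reproduction targets. Fractions
outside [0, 1] (currents drifting across solution changes) are reported
unclipped, with a warning. Group summaries give n, median, mean and SD
per construct; two-sided paired t-tests at α = 0.01 compare groups, raw
by default with an optional Bonferroni correction.

## Synthetic data

Generators are deterministic functions of (parameters, seed); each draws
from an independent substream keyed by a stable hash of the generator
name, so analyses never share noise.

* **MALS**: forward-model M_w times (1 + ε), ε ~ N(0, CV), independent
  per step and replicate. Noise is proportional because light-scattering
  error scales with signal; the 2% default CV is a modelling choice (the
  original per-point errors are not published in usable form), and
  it doubles as the detection-limit resolution. Noiseless mode is exactly
  the forward model.
* **Spectra**: log-normal-in-wavelength profile (mode exactly at the
  requested peak, asymmetric red tail as real tryptophan emission has)
  plus additive Gaussian noise. Only peak position and amplitude are
  contract-bearing; the shape family is a stand-in.
* **Patch traces**: piecewise-exponential approach (τ default 5 s) to the
  epoch targets implied by the requested fraction triplet and a total
  recovery amplitude (default −1 nA; an absolute scale is needed because
  the fractions sum to 1), plus optional global linear drift and additive
  Gaussian noise, sampled every 3 s over the canonical
  EGTA/Ca/R1/washout/R2 schedule.

What passing tests show — and what they do not: generator→analyzer
closure proves the estimators are consistent with their own forward
models (exact in the noiseless limit, unbiased at the stated noise), and
the fit round trips prove the published constant sets are recoverable
from data they generate under the stated gradient. None of this certifies
behaviour under real-instrument systematics (concentration
miscalibration, incompetent protein fractions, filter distortion of blue
spectral edges), which the generators deliberately do not simulate.

## Problem sizes and defaults

Round-trip fits use the 41-step gradient with 1 replicate (noiseless) or
5 replicates at 2% CV over 5 trials (stochastic checks); the conservation
property runs 1000 randomized models; patch-recovery closure runs 100
randomized records. The detection-limit grid is 15 points over
log K_A ∈ [5, 12]. All stochastic tests fix their seeds.

## Known limitations

* The 2SKp/2CaM constant is implemented monomer-referenced
  (2P + 2C ⇌ P₂C₂). If it is instead read as dimerization of preformed
  P-C, the equivalent monomer-referenced value is that constant plus
  twice the 1:1 log K_A; the conversion is a one-liner on the model and
  the choice is flagged here rather than hidden.
* Absolute interior M_w values depend on the assumed injection series and
  are therefore not anchored to published interior readings.
* Constants flagged as outside the detection limit are recoverable only
  as lower bounds; round-trip tests skip exact assertions for them.
* The Beer–Lambert module stores the published CaM extinction values at
  277 nm (3020, 5960) as fixtures: they follow a literature convention
  that the aromatic-count prediction (2×1490 = 2980 for two tyrosines)
  does not reproduce, and no attempt is made to derive them.
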