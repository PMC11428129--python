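# Methods

`rpsb2pa` analyses two-photon absorption (2PA) of retinal protonated Schiff
base (RPSB) chromophores — the light-absorbing unit of rhodopsin — and of
quasi-linear charge-transfer chromophores generally. It covers the chain
from microscopic response quantities (second-order transition moments) to
the macroscopic cross sections an experimentalist would measure, plus the
benchmarking arithmetic used to compare density-functional methods against
a coupled-cluster reference. This note records the model, the conventions
frozen into the code, and what the synthetic data generator does and does
not emulate.

## Microscopic model: sum-over-states two-photon moments

For a degenerate two-photon transition |0⟩ → |f⟩ at photon energy
ω = ω_f/2, the Cartesian components of the second-order transition moment
are built from the electronic manifold by the standard sum over states

    S_αβ = Σ_n [ ⟨f|μ̄_α|n⟩⟨n|μ̄_β|0⟩ + ⟨f|μ̄_β|n⟩⟨n|μ̄_α|0⟩ ] / (ω_n − ω_f/2)

symmetrized over the two photon orderings. The dipole operators enter in
*fluctuation* form, μ̄ = μ − ⟨0|μ|0⟩: the ground-state permanent dipole is
subtracted from every diagonal element of the dipole matrix. This choice is
not cosmetic — it makes the n = 0 term vanish identically, renders the
moment independent of the coordinate origin (a pure gauge choice), and is
what allows the two-state model to emerge from the n = f term alone. Both
properties are enforced as tests.

The engine assumes real wavefunctions, i.e. a dipole matrix symmetric in
the state indices, so the left moment (for |f⟩→|0⟩) is exactly the
transpose of the right one and the tensor is Hermitian. Left/right
asymmetry, as produced by coupled-cluster response solvers, is a property
of the solver and cannot be reconstructed from a dipole matrix; the
non-Hermitian averaging path is therefore exercised with explicitly
constructed left/right pairs, never through the SOS engine.

### Resonance guard

SOS denominators diverge when an intermediate state approaches the photon
energy ω_f/2 (resonance enhancement). Manifolds with any state within a
guard of the photon energy are rejected with a hard error rather than a
warning, because a near-resonant few-state sum is numerically meaningless
rather than merely imprecise. The default guard is 0.0095 au ≈ 0.26 eV,
configurable per call.

## Rotational averaging

For an isotropic sample and two identical, parallel linearly polarized
photons, the orientation average of (e·L·e)(e·R·e) over uniform rotations
is the rank-4 isotropic contraction

    δ = (1/15) [ Tr(L)·Tr(R) + Σ_αβ L_αβ R_αβ + Σ_αβ L_αβ R_βα ].

`average_hermitian` accepts a single symmetric moment (L = Rᵀ, tolerance:
relative Frobenius asymmetry ≤ 1e-8, harder asymmetry redirects the caller
to the non-Hermitian route) and `average_nonhermitian` the general pair;
the latter reduces exactly to the former in the Hermitian limit. Negative
non-Hermitian averages, possible for pathological left/right pairs, are
returned as-is with a logged warning — clipping would hide the pathology.
`average_numerical` estimates the same quantity by Monte-Carlo sampling of
uniform SO(3) rotations and is the independent oracle used by the tests
(agreement within 3 standard errors is asserted on batches of random
tensors).

### Two-state model

On a ground+final manifold the SOS collapses to the closed form

    δ_2state = 16 / (15 ω_f²) · [ |μ01|² |Δμ|² + 2 (μ01·Δμ)² ]

which at collinearity becomes (16/5)·|μ01|²|Δμ|²/ω_f². The angle factor is
derived once from the averaging contraction above and frozen here; exact
equality between `two_state_delta` and the SOS+averaging pipeline on
two-state manifolds is the defining contract and is tested to
floating-point tolerance. Charge-transfer chromophores like RPSB are
dominated by this term — which is why δ trends track Δμ trends so closely —
and the benchmark layer quantifies that with a Pearson correlation between
recorded δ values and the collinear two-state estimate built from recorded
magnitudes (collinearity is assumed there because tabulated data carry only
magnitudes; for a quasi-linear chromophore the error of that assumption is
a few percent in the estimate and negligible in the correlation).

## Macroscopic conversion

The peak 2PA cross section for a Lorentzian band is

    σ = N π³ α a₀⁵ / c · ω² · g_peak(Γ) · δ,    g_peak = 1/(π Γ)

with ω = ΔE/2 (degenerate photons), Γ the lifetime broadening, α the
fine-structure constant, a₀ the Bohr radius, c the speed of light, and N an
integer prefactor. Defaults are Γ = 0.1 eV and N = 4. σ is the *peak* value
of the band, not an integral. Results are reported in Göppert-Mayer units,
1 GM = 1e-50 cm⁴ s/photon.

Published renderings of this conversion differ in where factors of π and 2
live (half- vs full-width conventions, peak normalization of g). The
convention above was fixed by requiring the packaged reference dataset's
(δ, ΔE) → σ triples to be reproduced: with it, the three spot rows used as
calibration checks agree to 0.02–0.43%, and all 35 rows agree within 1%
plus half a unit of the single printed σ decimal. The residual beyond 1% on
a handful of small-σ rows (worst: 0.074 GM on a 6.4 GM row) traces to the
source table itself: its implied per-row conversion constants scatter by
±1.8% because the tabulated σ were computed from unrounded δ values and
printed to one decimal. No fixed physical constant can do better than that
scatter.

All internal computation is in Hartree atomic units; eV, Debye and GM
appear only at the I/O boundary (CODATA 2018 constants, exported to
`docs/constants.txt` for audit).

## Reference dataset and benchmarking

The packaged dataset holds seven RPSB5 structures (the five-double-bond
truncated native 9,13-dimethyl chromophore and six de/methylated analogues,
two of them in both planar Cs and twisted conformations) under five
methods: the RI-CC2 coupled-cluster reference and four TD-DFT functionals
(M11, MN15, CAM-B3LYP, BHandHLYP). Each row carries ΔE [eV], δ [au],
σ [GM], and the dipole magnitudes μ01, Δμ, μ00, μ11 [D]. Aggregate rows are
never stored — the benchmark layer recomputes them:

- **MAE** per property: unweighted mean of |method − reference| over the
  seven structures. Recomputed from the stored rows, 25 of the 28 published
  per-functional MAEs reproduce exactly at printed precision and three land
  one unit of the last printed digit away (the published aggregates were
  formed before rounding); the tests pin both facts.
- **Underestimation factors**: min/max over structures of
  reference/method ratios, reported at one decimal (M11 δ factor: 3.8–5.3).
- **Relative changes** vs the native 9,13-dimethyl baseline and trend
  orderings (descending, alphabetical tie-break with a logged note).
- **Two-state correlation** per method block (r ≥ 0.99 for every method in
  the packaged dataset).

Validation invariants on records: positivity, and the triangle inequality
|μ00 − μ11| ≤ Δμ ≤ μ00 + μ11 forced by Δμ being a vector difference
(checked with a 0.005 D slack for printed rounding). Note that Δμ is stored
as printed, never recomputed from the magnitudes — the scalar difference of
magnitudes is *not* |Δμ| unless the dipoles are collinear.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, so
every stage is testable without external electronic-structure data. Default
ranges mirror the coupled-cluster block of the reference dataset: S1
excitation energy 2.5–3.1 eV, |μ01| 10–12.5 D, μ00 5.5–8.5 D, μ11 1–6 D,
μ01 within 15° of the Δμ line. Geometry: a molecular long axis is drawn
isotropically; both permanent dipoles lie on it (so Δμ is exactly axial —
the quasi-linear idealization) and μ01 is drawn uniformly in the
collinearity cone around it. Higher states get energies 0.8–1.2 eV apart
and couplings that decay geometrically (factor 0.3 per state), keeping the
SOS dominated by the two-state term as in the real chromophores, and always
outside the S1 resonance guard.

Method biases mimic the known TD-DFT-vs-CC pattern (ground-state dipoles
underestimated, excited-state dipoles overestimated, hence Δμ shrunk;
excitation energies shifted up): a bias is an energy shift plus a scale on
the excited-state fluctuation dipole, optionally with Gaussian noise
applied to ΔE and to dipole *vectors* before δ and σ are recomputed through
the SOS pipeline — so generated records are always internally consistent
and bias recovery by the benchmark layer is exact at zero noise (tested).
Default bias palette: an unbiased reference plus two DFT-like methods
(+0.19 eV/×0.57 and +0.25 eV/×0.37), matching the magnitude of the M11- and
MN15-class errors in the reference dataset.

What the generator does **not** emulate: actual electronic structure (no
orbitals or basis sets), left/right coupled-cluster asymmetry, vibronic
structure, non-degenerate (two-color) photons, circular polarization, or
correlated errors between properties within a method. Passing tests on
synthetic data therefore demonstrate the correctness of the analysis
arithmetic under the stated statistical model, not the accuracy of any
electronic-structure method.

## Numerical choices

- Hermitian symmetry tolerance: relative Frobenius asymmetry ≤ 1e-8.
- Rotation invariance holds to ≥ 10 significant figures and is tested so.
- Monte-Carlo averaging uses ≥ 1000 orientations (enforced); tests use
  2·10⁴–10⁵ with a 3-standard-error band.
- Ordering ties break alphabetically with a logged note.
- Ratio ranges and MAE rows are reported at the reference table's printed
  precision; raw values are retained in the JSON report.
- Problem sizes throughout (7 structures, manifolds of 2–5 states, 20–25
  random tensors per property test) keep the whole suite around a couple of
  seconds while leaving every contract exactly testable.

## Known limitations

- The few-state engine cannot produce genuine left/right-asymmetric
  moments; CC-style asymmetry is injected synthetically where needed.
- The two-state correlation assumes collinear μ01 and Δμ; for strongly bent
  chromophores the estimate (not the machinery) would degrade.
- The δ→σ conversion is a peak-height convention; band-integrated cross
  sections and non-Lorentzian lineshapes are out of scope.
- Reference data are consumed as given; the underlying response
  calculations are outside the package's scope.
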