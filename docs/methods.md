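# Methods

## Physical model and assumptions

`ferroheat` models heating of superparamagnetic nanoparticle ensembles in the
linear-response (Debye) regime with a Langevin saturation correction. The
assumptions, in decreasing order of importance:

- **Néel relaxation only.** Particles are treated as mechanically fixed in
  tissue, so Brownian rotation contributes nothing; the moment reorients over
  the anisotropy barrier E = πKD³/6 (sphere volume × K) with time constant
  τ = τ₀·exp(E/k_BT). Hysteresis (Stoner–Wohlfarth) losses, eddy currents and
  interparticle dipolar interactions are out of scope.
- **Monodisperse spheres.** D is a single value, not a distribution. Real
  ferrofluids have log-normal size spreads that broaden and lower the peak of
  P_s(D); computed peak values are therefore upper bounds for a real sample
  with the same median size.
- **First-order relaxational response.** χ(ω) = χ₀/(1 + jωτ) with the static
  susceptibility reduced by field saturation, χ₀ = 3χ_i L(ξ)/ξ. This hybrid
  (a linear-response spectrum scaled by an equilibrium nonlinearity) is the
  standard engineering approximation in this field; it is accurate for
  ξ ≲ a few and progressively overestimates dissipation as ξ grows.
- **Room-temperature, bulk-like material constants.** K(x), M_s(x), ρ(x) are
  room-temperature values; no self-heating feedback on the material
  properties, and no modelling of the tissue temperature rise itself (the
  42–43 °C therapeutic target is an application constraint, not a model
  output).

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| x | Co²⁺ atomic fraction | — | 0–1 (K model extends to 1.1) |
| D | particle diameter | search 1–20 nm | m |
| ε | packing volumetric fraction | 0.1 | — |
| τ₀ | Néel attempt time | 10⁻⁹ | s |
| T | temperature | 300 | K |
| H | field amplitude | study grid 10–50 kA/m | A/m |
| f | field frequency | study grid 100–500 kHz | Hz |
| C | biological limit H·f | 5×10⁹ | A·Hz/m |
| threshold | minimum useful (P_sM)_l | 10 | W/g |
| saturation_rel_gain | window saturation rule | 0.05 per grid step | — |

T is not printed alongside the reference tables; 300 K ("room temperature",
the condition of the material anchors) reproduces all of them to within their
print resolution, and is exposed as a parameter.

All computation is strict SI. The conventional "W/g" output scale is the SI
W/kg divided by 1000 and is labelled explicitly wherever it appears.

## Material-property model

The anchor table (nine compositions, x = 0–1.1) ships as a packaged CSV.
Only the anchors are authoritative; between them:

- **K(x)**: shape-preserving monotone piecewise-cubic (PCHIP) interpolation.
  Exact at every anchor, C¹-continuous, and — because the anchor sequence
  rises to x = 0.67 and falls after — guarantees the single interior maximum
  there without inventing a parametric fit form.
- **M_s(x) = 480 − 55x kA/m**: the stated linear composition dependence,
  fixed by the magnetite and cobalt-ferrite end members. All intermediate
  anchors then agree to their print resolution (nearest kA/m).
- **ρ(x) = (5.24 + 0.05x)×10³ kg/m³**: no functional form is stated in the
  source material; the line through the end members matches every anchor
  after rounding, so nothing finer is identifiable from the data.

Users with measured anchors should substitute them
(`MaterialModel.from_csv`), since nanoparticle K and M_s depend on synthesis
route and size.

## Numerical choices

- **Langevin function**: closed form coth ξ − 1/ξ for |ξ| > 10⁻⁴, odd series
  ξ/3 − ξ³/45 below (the closed form loses ~10⁻⁸ relative accuracy to
  cancellation near the switch; the series is exact to ~10⁻¹⁷ there). The
  static factor 3L(ξ)/ξ uses the matching series 1 − ξ²/15.
- **Debye factor**: ωτ/(1+(ωτ)²) evaluated as 1/(u + 1/u), which cannot
  overflow even when τ is astronomically large (u ~ 10¹²⁰ occurs inside the
  study box at high K and D). The Néel exponent is checked against the
  double-precision exp limit and raises an explicit overflow error beyond it.
- **Diameter optimizer**: coarse scan at ≤0.05 nm over the search interval
  (robust to any non-unimodality), then bounded scalar minimization of −P_s
  on the bracketing interval to ~10⁻⁴ nm. The reported peak power is the
  model re-evaluated at the returned diameter (same code path), so the pair
  (D_M, P_sM) is self-consistent by construction. Tables round D_M to 0.1 nm
  and powers to 2 decimals; JSON mirrors keep full precision. An optimum
  within one coarse step of an interval end is flagged (and warned) as a
  boundary optimum. If two peaks ever tied, the scan would keep the smaller
  diameter; this does not occur on the study box, where P_s(D) is unimodal
  (asserted by test).
- **Bio-limit frequencies**: f_l = C/H exactly, never the display-rounded
  integer kHz, so H·f_l = C holds to machine precision. Consequently the
  H = 30 kA/m row uses 166.67 kHz where the published table used 167 kHz
  (a ~0.2% difference in the resulting powers).

## Operating-window heuristic

The published recommendations were made by visual inspection of the
(P_sM)_l-vs-H curves. The package encodes them as an explicit two-rule
procedure on the amplitude grid: the lower bound is the smallest H whose
constrained peak power meets the threshold (default 10 W/g, the lower edge
of the stated 10–15 W/g useful range); the upper bound is the last H before
a grid step whose relative gain falls below `saturation_rel_gain` (default
5%), else the hardware cap (50 kA/m — large amplitudes at 10⁵ Hz are hard to
generate). All three knobs are configurable. With defaults the rule
reproduces the published windows at x = 0, 0.1 and 0.2; at x = 0.05 it
extends the window to 50 kA/m where the publication stopped at 40 (the
40→50 step still gains 7.8%, above any cutoff that would also preserve the
x = 0 window — the two published judgments are not consistent with a single
gain cutoff). For x ≥ 0.4 the curves are far from saturation and the rule
returns hardware-capped windows; mismatches there are reported by the
comparison products rather than treated as errors.

## Known data inconsistency

One published bio-limit cell (H = 30 kA/m, x = 0.2: 20.07 W/g) deviates by
~10% from the model value (22.18 W/g) while the other 39 cells of that table
agree within 2%, and the printed x = 0.2 column is non-smooth exactly there.
It is treated as a misprint: the packaged reference CSV keeps the printed
value, and the comparison report flags the cell.

## What the tests do and do not show

The suite verifies internal equivalence of the two loss-power formulations
(product form vs πμ₀χ″fH²/ρ, 10⁴ quasi-random points, 10⁻¹² relative),
optimizer agreement with an independent dense-grid scan, reproduction of the
published tables at their print resolution (0.15 nm / 2%), and the stated
qualitative facts (peak sharpness, monotonicity in H and f, power and
diameter minima at x = 0.8, frequency ordering). Passing these shows the
implementation is faithful to the stated model and its published outputs —
not that the model predicts heating in real tissue, where polydispersity,
Brownian relaxation in fluid compartments, dipolar interactions and
temperature feedback all matter.

## Problem sizes

Default products evaluate 8 compositions × 3 frequencies × (≈381-point
coarse scan + local refinement) per optimization and a 5-amplitude bio-limit
grid; a full `reproduce` run is a few seconds on one core. Brute-force
test oracles use 0.5×10⁻³ nm diameter grids (≈38 000 points, vectorized).
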