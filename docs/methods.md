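# Methods

## Model

### Configuration space

A local contour element is a similarity frame
`q = (x, y, θ, σ) ∈ SIM(2)`: position in the plane, orientation
`θ ∈ (−π, π]`, and log-thickness `σ` (physical thickness `κ = e^σ`).
The group law is realized through the 3×3 homogeneous matrix

```
[ e^σ cos θ   −e^σ sin θ   x ]
[ e^σ sin θ    e^σ cos θ   y ]
[ 0            0           1 ]
```

so products, inverses and the matrix round-trip are exact group
operations; angles are wrapped to `(−π, π]` after every operation.

### Horizontal distribution and metric

The left-invariant frame is

```
X1 = e^σ (cos θ ∂x + sin θ ∂y)     advance along the contour
X2 = e^σ (−sin θ ∂x + cos θ ∂y)    sideways slide (forbidden)
X3 = ∂θ                            turn
X4 = ∂σ                            rescale
```

Admissible (horizontal) curves satisfy `q̇ = u1 X1 + u3 X3 + u4 X4`,
i.e. they annihilate the contact form
`ω = e^{−σ}(−sin θ dx + cos θ dy)`. The cost is
`∫ √(u1² + α² u3² + β² u4²) dt`; all numerics use the model case
`α = β = 1` (the `MetricParams` dataclass carries general positive
weights for bookkeeping and validation). The nonzero brackets are
`[X1,X3] = −X2`, `[X1,X4] = −X1`, `[X2,X3] = X1`, `[X2,X4] = −X2`;
since `[X3,X1] = X2`, the set `{X1, X3, X4, [X3,X1]}` spans the full
tangent space and the structure is bracket-generating (step 2), which
guarantees that any two configurations can be joined by a horizontal
path.

### Extremal flow

The Pontryagin maximum principle with frame momenta
`h_i = ⟨p, X_i⟩` gives the normal Hamiltonian
`H = h1² + h3² + h4²` and, at arc-length parametrization `H = 1`, the
8-dimensional system

```
ẋ = h1 e^σ cos θ     ḣ1 =  h3 h2 + h4 h1
ẏ = h1 e^σ sin θ     ḣ2 = −h3 h1 + h4 h2
θ̇ = h3               ḣ3 = −h1 h2
σ̇ = h4               ḣ4 = −h1²
```

Conserved along the flow: `H` and the chart momenta
`g1 = e^{−σ}(h1 cos θ − h2 sin θ)`, `g2 = e^{−σ}(h1 sin θ + h2 cos θ)`.
Abnormal extremals are the vertical lines `σ = ±t` (also normal, with
`h = (0,0,0,±1)`). Fiber geodesics (`h1(0) = h2(0) = 0`) are linear,
`θ = h3(0) t`, `σ = h4(0) t`, and lose optimality at `t = π/|h3(0)|`;
the two extremals with `±h3(0)` meet at wrapped `|θ| = π` (a Maxwell
point). Since `ḣ4 = −h1² ≤ 0`, `h4` is non-increasing; when
`h1² + h2² > 0` and `h4(0) < 0` the horizontal momenta decay,
`h3² + h4² → 1`, and the spatial projection stays in a bounded disc —
this is what makes scale-contracting association-field curves spatially
local. The Poisson-bracket matrix `{h_i, h_j}` has determinant
`(h1² + h2²)²`: rank 4 off the fiber axis, rank 0 on it.

## Numerical choices

- **Exponential map**: `scipy.integrate.solve_ivp`, DOP853 with
  `rtol = 1e−12`, `atol = 1e−14`, dense output. The tight tolerances
  are needed because the chart first integrals contain a factor
  `e^{−σ}` that amplifies state error on scale-contracting extremals;
  at these settings the worst observed drift of `(H, g1, g2)` over
  `T = 10` on random unit covectors is ~2e−10 (test budget 1e−8).
  `exponential_map` refuses covectors off the unit level set unless
  `renormalize=True`.
- **Shooting inner loop**: a numba-jitted fixed-step RK4 at 400 steps
  per unit time evaluates the residual inside `scipy.optimize.root`
  (hybr). Fixed-step RK4 keeps the residual smooth in the unknowns
  (adaptive step selection would introduce kinks), and the jitted loop
  makes 32 starts ≈ 0.4 s per target. The final reported trajectory is
  always re-integrated with the high-accuracy DOP853 route and the
  residual re-measured against it.
- **Shooting parametrization**: unknowns `(a, b, h2, τ)` with
  `(h1, h3, h4) = (cos b cos a, cos b sin a, sin b)` on the unit level
  set and `T = |τ|`. 32 starts: 16 Fibonacci-sphere directions, each
  with `h2 = 0` at the lower-bound time guess and `h2 = ±0.6` at 1.5×
  that guess, triaged by initial residual. Candidates whose total
  `θ`-variation exceeds `2π` are discarded (past the rotational Maxwell
  set, hence non-minimizing); among the converged candidates the
  smallest time is kept, and the search stops early if that time meets
  the certified lower bound. Targets on the fiber `x = y = 0` with
  `|wrap θ| ≤ π` are answered in closed form (provably optimal, inside
  the cut time). Non-convergence is reported honestly
  (`converged=False`, best residual); `sr_distance` raises on it.
- **Distance lower bound**: along unit-speed horizontal curves
  `|θ̇| ≤ 1`, `|σ̇| ≤ 1` and planar speed `≤ e^{σ(0)+t}`, giving the
  left-invariant certified bound
  `max(|Δσ|, |wrap Δθ|, ln(1 + r·max(1, e^{−Δσ})))` with `r` the planar
  offset in the start frame. The spatial term is what lets the
  grouping-scene generator *certify* that all background pairs are
  separated by more than the threshold without solving any BVP.
- **Maxwell meeting**: the two trajectories `±h3(0)` are integrated
  simultaneously and the meeting time is located with `brentq` on
  `sin((θ₊ − θ₋)/2)`; full coincidence of all four coordinates is then
  verified below 1e−6.
- **Gabor lifting**: the bank samples the even profile
  `G_{θ,σ}(v) = e^{−2σ} e^{−|v_{θ,σ}|²} cos(2 y_{θ,σ})` with
  `v_{θ,σ} = e^{−σ} R(−θ) v`, truncated at 3 dilated units (envelope
  < 1.3e−4). Evenness makes the profile π-periodic in θ, so the grid
  covers `[0, π)`. Kernels are integrated over pixel footprints
  (supersampled when the pixel pitch is coarse relative to `e^σ`) so
  fine-scale kernels do not alias to deltas; every kernel keeps the
  analytic DC gain `π/e` regardless of `(θ, σ)`. Convolution uses
  edge-inclusive reflective padding, identical between the direct
  (`scipy.ndimage`) and FFT routes. Feature selection is the argmax of
  `|O|` over the `(θ, σ)` fiber with a lexicographic tie-break and an
  explicit `no_response` flag.
- **Scale calibration**: the argmax log-scale of the bank determines
  thickness only up to the profile's internal normalization, so a
  constant offset `argmax_σ(reference bar of width w) − ln w` is
  measured once per bank/pixel-size and stored
  (`calibrate_sigma_offset`); downstream σ values are physical
  log-widths.
- **Boundary detection for inpainting**: candidate pixels are the
  one-pixel ring around the damaged mask with intensity above half the
  off-mask maximum, grouped into connected components. Because a filter
  centered on the ring sees the void, orientation/scale are read a
  little *outward*: the probe steps away from the mask centroid by 1.25
  estimated widths, twice, re-estimating width each time. On the bar
  fixtures this recovers `θ` and `σ = ln(width)` exactly on the grids.
- **Completion**: detected endpoints are oriented into the mask,
  connected pairwise by shooting (the arrival frame continues outward,
  `θ_b + π`), matched greedily by ascending geodesic time, and the
  geodesics are rendered as stamped discs of diameter `e^{σ(t)}`
  clipped to the mask, so pixels outside the damaged region are never
  modified.

## Synthetic data generator — scope

`make_curve_image` rasterizes polyline strokes with linearly
interpolated width (union over segments, distance-to-segment test,
optional seeded Gaussian noise clipped at 0) and returns centerline
ground truth `{x, y, θ, log-width}`. `corrupt_with_disc` blanks a disc
in retinal coordinates and returns the boolean mask. The generator
covers piecewise-linear strokes only; it is meant for fixtures and
calibration, not for photorealistic or curved-boundary test imagery.

## Parameters and defaults

| parameter | default | rationale |
|---|---|---|
| integrator tolerances | 1e−12 / 1e−14 | keep `e^{−σ}`-amplified invariant drift ≤ 1e−10 over T = 10 |
| shooting starts | 32 | 100% recovery on seeded generate-and-recover benchmarks (T* ≤ 2.5) |
| RK4 steps per unit | 400 | residual accuracy ~1e−10 at T ≤ 2, smooth in the unknowns |
| bank θ samples | 16 (default) / 24 (completion) | grid step π/16 ≈ 11°, π/24 ≈ 7.5° |
| bank σ range/step | [−1, 1.8] / [−0.6, 1.4] at 0.1 | covers thicknesses ~0.4–6 px-independent units |
| support radius | 3 | Gaussian envelope < 1.3e−4 at truncation |
| probe factor / iterations | 1.25 / 2 | steps the reader clear of the void before measuring |
| grouping spacing / separation | 0.1 / 0.18 | foreground spacing strictly below the certified background separation |

## Limitations

- The shooting solver returns the best *converged candidate*; global
  optimality is certified only when the returned time meets the
  distance lower bound or the target lies on the fiber within its cut
  time. Elsewhere `sr_distance` is an upper bound that is empirically
  tight on generate-and-recover benchmarks.
- Completion pairs endpoints greedily by geodesic time; configurations
  with many interleaved contours may require global matching.
- Boundary detection assumes contours brighter than the background and
  a damaged region that is exactly known (the mask); it reads features
  from the intact side only.
- The lifting measures orientation modulo π (even profile); the
  direction of traversal is resolved only by the completion step's
  orient-into-mask rule.
- The metric weights α, β enter validation and cost bookkeeping, but
  the extremal flow is implemented for the model case α = β = 1.
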