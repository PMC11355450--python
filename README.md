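# sim2sr — sub-Riemannian contour completion on SIM(2)

`sim2sr` models how an interrupted image contour can be continued in a
geometrically principled way. Early visual cortex is often described as
lifting the retinal image into a space of local features — each point of
a contour is represented not just by its position `(x, y)` but also by
its orientation `θ` and its thickness `κ = e^σ`. This package works in
that 4-dimensional feature space, the similarity group **SIM(2)** of
planar translations, rotations and dilations, and restores missing
contour pieces along *sub-Riemannian geodesics*: curves of minimal cost
whose velocity is constrained to the physically meaningful directions
(advance along the contour, turn, and rescale — but never slide
sideways).

The package provides four layers:

1. **Group and geometry** (`sim2sr.group`): SIM(2) elements
   `q = (x, y, θ, σ)`, their products and inverses, the left-invariant
   frame `X1..X4`, the contact form whose kernel is the horizontal
   distribution, structure constants, and the bracket-generating
   (Hörmander) condition.
2. **Hamiltonian flow** (`sim2sr.flow`): the Pontryagin maximum
   principle reduces geodesics to an 8-dimensional ODE for
   `(q, h1..h4)` with Hamiltonian `H = h1² + h3² + h4²`. The module
   integrates this flow (the sub-Riemannian exponential map), computes
   first integrals, Maxwell points, cut times of fiber geodesics, the
   Poisson-bracket matrix and the vertical asymptotics.
3. **Shooting** (`sim2sr.shooting`): a multi-start boundary-value
   solver inverting the exponential map — given a target configuration,
   find the initial covector and time whose geodesic reaches it — plus
   a certified lower bound on the sub-Riemannian distance.
4. **Imaging** (`sim2sr.lifting`, `sim2sr.synthetic`,
   `sim2sr.applications`, `sim2sr.io`, `sim2sr.cli`): an even Gabor
   filter bank lifting images to orientation–scale scores, synthetic
   curve fixtures, association-field fans, a perceptual-grouping scene
   generator, and geodesic inpainting of disc-corrupted contours.

## Worked example

Integrate a geodesic, then solve the inverse problem by shooting:

```python
import numpy as np
from sim2sr import Covector, GroupElement, exponential_map, shoot

# A covector with h2 = h3 = 0 keeps theta = 0: the geodesic lives in the
# (x, sigma) plane, a hyperbolic-plane geodesic. With h4(0) < 0 the scale
# contracts and the spatial advance saturates.
traj = exponential_map(Covector(0.6, 0.0, 0.0, -0.8), 10.0)
print(np.round(traj.endpoint().as_array(), 6))
# [ 0.333333  0.        0.       -9.894639]
print(traj.conservation_drift())   # drift of the first integrals H, g1, g2
# [2.37032616e-13 2.08550954e-10 0.00000000e+00]

# Inverse problem: connect the identity to a target configuration.
res = shoot(GroupElement(1.2, 0.4, 0.8, -0.3))
print(res.converged, round(res.T, 6), res.residual)
# True 1.626727 1.132179601611688e-09
print(np.round(res.h0.as_array(), 6))
# [0.804138 0.116549 0.444382 0.394826]
```

Contour completion end to end — build a width-2 bar, punch a disc of
radius 1.2 out of it, detect the two boundary configurations, connect
them by a geodesic and repaint the gap:

```python
import math, numpy as np
from sim2sr.synthetic import CurveSpec, make_curve_image, corrupt_with_disc, calibrate_sigma_offset
from sim2sr.lifting import GaborBank
from sim2sr.applications import complete_contours

spec = CurveSpec(waypoints=((-6.0, 0.0), (6.0, 0.0)), width_profile=(2.0, 2.0))
img, _ = make_curve_image(spec, shape=(96, 96), pixel_size=0.125)
corrupted, mask = corrupt_with_disc(img, (0.0, 0.0), 1.2)

bank = GaborBank(theta_grid=np.arange(24) * math.pi / 24,
                 sigma_grid=np.linspace(-0.6, 1.4, 21))
bank = calibrate_sigma_offset(bank, width_ref=2.0, pixel_size=0.125, shape=(96, 96))

restored, report = complete_contours(corrupted, mask, bank=bank)
for q in report.endpoints:
    print(np.round(q.as_array(), 4))
# [-1.1042  0.      0.      0.6931]      <- (x, y, theta, sigma); e^0.6931 = 2
# [ 1.1042  0.      3.1416  0.6931]
print(report.pairs, [round(d, 4) for d in report.distances])
# [(0, 1)] [1.0546]

truth = img.intensities[mask] > 0.5
got = restored.intensities[mask] > 0.5
print(np.logical_and(truth, got).sum() / np.logical_or(truth, got).sum())
# 0.9428571428571428     (intersection-over-union inside the damaged disc)
```

The detected endpoints recover the bar's log-thickness `σ = ln 2` and
horizontal orientation exactly on the filter grids; the connecting
geodesic has length ≈ 1.05 (the bar moves at spatial speed
`e^σ ≈ 2`, so the ≈ 2.2-unit gap costs about half that in arc length).

The same pipeline is scriptable from the command line:

```bash
sim2sr make-fixture --waypoints "-6,0;6,0" --widths 2,2 --pixel-size 0.125 \
    --disc 0,0,1.2 --out bar.png --mask-out mask.png
sim2sr complete --image bar.png --mask mask.png --pixel-size 0.125 --out restored.png
sim2sr connect --target 0,0,1.5707963,0        # quarter-turn: T = pi/2
sim2sr grouping-scene --seed 0 --out scene.json --png scene.png
```

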