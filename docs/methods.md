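# Methods

## Model and assumptions

MACDE poses boundary detection as per-section global minimization of an
external energy over a polar coordinate system anchored at a user seed
point.  The operative assumption is **star-convexity about the seed**: every
ray from the seed crosses the object boundary exactly once, so one boundary
point per angular wedge suffices and the per-section winners, ordered by
angle, form a simple closed polygon.  Objects violating this (e.g. deeply
folded shapes where a ray crosses the boundary three times) are outside the
model; the method then returns the boundary point nearest to an edge in each
wedge, which need not bound a sensible region.

The potential surface is the Euclidean distance map (EDM) of the Canny edge
set: zero exactly on detected edges, growing with distance from them.  Its
global per-ray minimum is the detected boundary regardless of intermediate
plateaus, which is why population-based search within a wedge is robust to
the local minima (noise edges, distant attractors) that defeat the greedy
snake's 5×5 window search.

The per-section fitness is **external energy only** (γ·D sampled
bilinearly).  No inter-section smoothness term couples the wedges: the
tension/rigidity internal energy belongs to the snake baseline, not to the
sectional optimizer.  The angular ordering of sections supplies the
coherence a smoothness term would otherwise enforce.  Consequence: an
isolated spurious edge inside one wedge can claim that wedge's snaxel; the
surrounding sections are unaffected.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `dg` | degrees per polar section | 15 (24 sections) | values not dividing 360 (e.g. 13) produce floor(360/dg)+1 sections with the last wedge truncated |
| `n_snakes` | initial concentric contours = per-section population size | 15 | ≥ 4 so three distinct DE donors exist |
| `r_min`, `r_max` | radial search band (px) | 0.1·min(h, w)/2 and the largest seed-centered disk inside the image | the r_max disk must fit in the image; violations report the admissible maximum |
| `generations` (G) | DE generations | 10 | stability-based early stop available via `stability_window`, off by default |
| `diff_factor` (F) | DE differentiation factor | 0.1 | (0, 2] |
| `crossover_rate` (CR) | DE crossover rate | 0.8 | [0, 1] |
| `gamma` | external-energy weight | 0.05 | scales fitness values, not the argmin |
| `median_window` | median denoising window | 3 | odd |
| `canny_sigma`, `canny_low`, `canny_high` | Canny scale and hysteresis thresholds | 1.3, 10, 30 | thresholds on raw gradient magnitude of 0–255 images; `canny_normalized` switches to fraction-of-max |
| snake `alpha`, `beta`, `gamma` | tension, rigidity, attraction | 0.01, 0.9, 0.05 | high rigidity reproduces the classical concavity failure |
| snake `window_half` | half-width of the greedy search window | 2 (5×5) | the classical greedy-snake convention |

## Design choices

**Polar (r, θ) encoding per section.**  Individuals are polar vectors, so
the DE box bounds *are* the section restriction: "ignore improper
solutions" becomes a deterministic clip (radius to the band, angle to
[θ_lo, θ_hi) via the nearest representable value below the upper bound),
preserving population size and guaranteeing exactly one snaxel per wedge.

**Midangle initialization.**  Contour k contributes to each section the
point at radius r_k on the section midangle.  Under rand/1/bin all initial
θ-components in a section are equal, so θ-differences are zero and the
angular coordinate stays at the midangle throughout: the search is
effectively radial along each section's bisector, with the wedge bounds
retained for trials perturbed by the repair step.  This matches the
one-boundary-point-per-ray geometry and keeps snaxels angularly equispaced.

**Forced crossover component.**  The literal binomial rule can return a
trial identical to its target (every uniform draw above CR).  The standard
convention of forcing one mutant component is the default;
`pure_binomial=True` restores the literal rule.  Crossover copies the
mutant component when rand ≤ CR.

**Greedy snake move rule.**  The textbook greedy step moves each control
point to the window position minimizing its *own* energy terms.  That rule
does not strictly guarantee a non-increasing total energy, because a move
also changes the neighbour terms the moved point appears in.  The default
`energy_scope="coupled"` scores a candidate by every total-energy term the
moved point participates in (its own tension/rigidity/external plus the
three neighbour terms), making each sweep exact coordinate descent with a
guaranteed monotone energy log; `energy_scope="local"` restores the
textbook rule.  Candidate positions are integer pixel offsets; points stay
put on ties, so a fixed point terminates the sweep loop.

**Preprocessing.**  Median filter and Gaussian smoothing use edge
replication at borders so the image frame never generates edges.  The
distance transform is the exact Euclidean transform (verified against a
brute-force nearest-edge scan).  Continuous fitness positions sample the
EDM bilinearly so DE sees a piecewise-smooth surface rather than a
staircase; at integer coordinates the sampled value is the pixel value
exactly.

**Metrics.**  `hausdorff` defaults to the directed form
max_a min_b ‖a−b‖, with the symmetric max-of-both-directions variant
available (the CLI reports both).  Masks are reduced to 8-connected
boundary pixels.  Rasterization fills by the even-odd scanline rule over
pixel centers, with centers exactly on the polygon boundary counted inside;
self-intersecting polygons warn and fill even-odd.  Empty-vs-empty masks
score J = D = 1 (continuity), empty-vs-nonempty 0.

## Synthetic phantoms

The generator emulates the benchmark imagery: a 160×160 five-pointed star
(outer/inner radii 60/25) whose concavities defeat the greedy snake; a
300×300 disk (radius 100) with additive Gaussian noise of σ = 0.04 on the
normalized [0, 1] intensity scale — σ on the raw 0–255 scale would be
visually negligible — rescaled and clipped to 0–255; and a 150×150
three-lobed union-of-disks blob with two-plus boundary concavities.  Masks
are exact noiseless geometry; every phantom is star-convex about its center
(lobes must contain the center, enforced), and foreground/background
intensities default to 200/0 so the edge step clears the 10/30 hysteresis
thresholds.  A stack mode produces smoothly scaled/drifting slice series
sharing one valid seed point.

What the phantoms do *not* emulate: CT/MR appearance (bias fields, partial
volume, texture), low-contrast boundaries, multiple nearby organs, or
non-star-convex anatomy.  Passing the phantom suite demonstrates the
optimization claims (concavity recovery, noise robustness, oracle-exact
kernels), not clinical segmentation accuracy.

## Numerical notes and benchmark sizes

- All randomness flows from one master seed through `numpy` seed sequences
  (one spawned stream per section), so runs are bitwise reproducible and
  the metadata JSON replays a run exactly.
- Non-finite fitness values are treated as +inf and never selected; points
  mapping outside the image evaluate to +inf.
- An empty Canny edge map aborts with a message suggesting threshold
  adjustment (the EDM would be infinite everywhere).
- Benchmarks use 10 segmentation seeds per phantom and 100 seeds for the
  DE/oracle checks; the DE sphere benchmark runs Np = 15, G = 40, F = 0.5,
  CR = 0.8 on [−5, 5]².  The discrete-optimization check uses an 11×11
  lattice fitness (trials rounded to the nearest cell): an integer-shifted
  quadratic bowl plus Uniform(0, 5) per-cell perturbation, large enough to
  create deceptive local cells while keeping a structured landscape — a
  uniformly random table would make the argmin a 1-in-121 needle that
  rewards sampling luck rather than optimization.  The exhaustive scan of
  all 121 cells is the oracle.

## Known limitations

- One snaxel per wedge caps angular resolution at 360/dg; fine boundary
  detail between rays (e.g. star tips) is cut by the polygon chord, which
  dominates the Hausdorff distance even at high Dice.
- Sections are independent: a missing edge in one wedge (occlusion, broken
  Canny chain) lets that wedge's snaxel latch onto any other edge in range.
- The greedy snake baseline is deterministic given its initialization; its
  known concavity/noise failures are reproduced, not mitigated.
- No topology changes: one seed, one closed contour.
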