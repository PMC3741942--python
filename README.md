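# macde

Segmentation of star-convex objects in 2-D grayscale images by **multiple
active contours guided by differential evolution** (MACDE), with the
classical greedy active contour (snake) as a baseline.

The package targets interactive organ/structure segmentation in medical-style
imagery (CT/MR slices, phantoms): the user supplies a single interior seed
point and the method finds the object boundary, including deep concavities
and noisy edges where a locally greedy snake stalls in local minima.  It also
segments whole stacks of sequential slices by reusing the one seed point.

## Method

A grayscale image *I* is reduced to a potential surface in three steps:
a 3×3 median filter, the Canny edge detector (σ = 1.3, hysteresis thresholds
T_l = 10, T_h = 30 on the 0–255 gradient scale), and the Euclidean distance
map *D* — each pixel's distance to the nearest edge pixel, zero exactly on
edges.

The plane around the seed point is divided into g polar sections of
*dg* degrees each (θ = 2π/g; dg = 15 → 24 sections).  Section *S_i* owns an
independent population *O_i* of *n* candidate boundary points encoded in
polar coordinates (r, θ), seeded from *n* concentric initial contours so the
population spans the whole radial band [r_min, r_max].  Each population is
evolved with classical differential evolution (rand/1/bin):

    V_i = X_r1 + F (X_r2 − X_r3)                      (mutation)
    U_ij = V_ij if rand_j ≤ CR else X_ij              (binomial crossover)
    X_i ← U_i iff f(U_i) < f(X_i)                     (greedy selection)

with trials restricted to the section's wedge and radial band (clip repair),
and fitness f = γ·D(x, y) sampled bilinearly (external energy only).  The
best individual of every section becomes one snaxel; connecting the winners
in angular order yields the closed output contour.  Defaults follow the
benchmark settings G = 10, F = 0.1, CR = 0.8, dg = 15, n = 15.

The baseline snake minimizes the discrete energy
E = Σ_i ½(α‖p_i − p_{i−1}‖² + β‖p_{i−1} − 2p_i + p_{i+1}‖²) + E_ext(p_i)
by greedy window search (α = 0.01, β = 0.9, γ = 0.05, 5×5 window).
Segmentations are scored with the Jaccard index J = |A∩B|/|A∪B|, Dice index
D = 2|A∩B|/(|A|+|B|), and the Hausdorff distance
H(A, B) = max_{a∈A} min_{b∈B} ‖a − b‖.

## Worked example

```python
from macde import MACDE, synthetic

img, truth = synthetic.make_star()           # 160x160 star, exact mask
result = MACDE(img, seed_point=(80, 80)).fit(seed=42)
print(result.summary())
for name, value in result.score(truth).items():
    print(f"{name}: {value:.4f}")
```

prints

```
MACDE segmentation results
==========================================
image shape            : (160, 160)
seed point (x, y)      : (80.0, 80.0)
sections (dg)          : 24 (15.0 deg)
snakes / section pop   : 15
DE G / F / CR          : 10 / 0.1 / 0.8
radial band [px]       : [8.00, 79.00]
fitness mode (gamma)   : edm (0.05)
rng seed               : 42
mean fitness start/end : 0.6675 / 0.0034
best fitness (max sec) : 0.0158

jaccard: 0.9055
dice: 0.9504
hausdorff_directed: 4.4721
hausdorff_symmetric: 15.0000
```

The mean population fitness (average distance-to-edge of all 360
individuals, times γ) drops from 0.67 to 0.003 over the 10 generations: the
populations collapse onto the star boundary.  Dice 0.95 against the exact
ground truth means the 24-snaxel polygon captures the star including its
concavities; the same phantom segmented with the greedy snake baseline
(`ActiveContour`, 42 control points) reaches only Dice ≈ 0.45 because the
rigidity term keeps it from entering the concavities.  The directed
Hausdorff distance (4.5 px) is dominated by the star tips between sampled
rays; the symmetric variant also measures the truth boundary against the
polygon and is therefore larger.

The same workflow is available from the shell:

```sh
macde phantom --kind star --out star/
macde segment --input star/image.png --seed-x 80 --seed-y 80 \
      --dg 15 --snakes 15 --generations 10 --F 0.1 --CR 0.8 \
      --rng-seed 42 --out seg/
macde eval --pred seg/mask.png --ref star/mask.png
macde segment-stack --input-dir slices/ --pattern "slice_*.png" \
      --seed-x 256 --seed-y 256 --out stackseg/   # one seed for all slices
```

`segment` writes the contour CSV, filled mask and overlay PNGs, a fitness
trace, and a metadata JSON that reproduces the run bit-for-bit.

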