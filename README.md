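# gfkuts

Automatic canopy segmentation for multispectral crop imagery, with
vegetation-index feature extraction and machine-learning estimation of
above-ground biomass.

## The problem

High-throughput phenotyping of rice trials needs plot-level biomass
estimates without destructive sampling. UAV-mounted multispectral
cameras (green, red, red-edge, near-infrared bands) see the canopy, but
every downstream number — NDVI, SAVI and friends, and the regressions
built on them — depends on first separating canopy pixels from soil,
water and weeds. Manual initialisation (as in classic GrabCut) does not
scale to thousands of plot images, and per-pixel colour clustering is
brittle under shadows, clipped highlights and sensor noise.

This package implements **GFKuts**, a fully automatic segmentation
pipeline, and the analysis chain around it:

1. **Montecarlo-sampled K-means trimap** — `l` pixels are sampled
   uniformly at random and 2-means-clustered in colour space. The larger
   cluster seeds the known-foreground mask T_F (canopy dominates plot
   imagery), the smaller seeds known-background T_B; everything else is
   uncertain (T_U). No user input.
2. **Iterative GrabCut** — alternating Gaussian-mixture colour models
   (K = 5 per class) and exact graph min-cut minimisation of

   E(α, k, θ, z) = U(α, k, θ, z) + V(α, z)

   with U the per-pixel negative log mixture likelihood under the
   pixel's own class and V the contrast-sensitive 8-neighbourhood
   smoothness term γ·exp(−β‖z_p − z_q‖²)/dist(p, q) over discordant
   pairs, β auto-estimated from mean neighbour contrast.
3. **Guided-filter feathering** — the hard mask is filtered with the
   multispectral composite as guidance (O(n), pure box means), producing
   a soft mask whose boundary follows leaf texture, then re-binarised by
   an adaptive (Otsu) threshold.
4. **Vegetation indices** — NDVI, GNDVI, DVI, CTVI, SAVI (L = 0.5),
   MSAVI and SR averaged over the canopy mask, one feature row per plot.
5. **Biomass models** — an elastic net minimising
   MSE + r·α·Σ|β_i| + ((1−r)/2)·α·Σβ_i² for genotype/production-system
   analysis, and a 7→15→1 tanh network trained with Levenberg–Marquardt
   (60/40 train/test split) for biomass estimation across the
   vegetative, reproductive and ripening stages.

A synthetic-scene generator with exact ground-truth masks and a
plot-level biomass table (two genotypes × lowland/upland systems × three
stages) makes the whole chain testable end to end.

## Worked example

```python
from gfkuts import (SceneSpec, generate_scene, run_gfkuts,
                    segmentation_metrics, compute_vi)

scene = generate_scene(SceneSpec(shape=(128, 128), canopy_fraction=0.6,
                                 noise_sd=0.05, shadow=True,
                                 system="upland", seed=42))
result = run_gfkuts(scene, l=800, n=5, r=4, epsilon=1e-3, seed=0)
m = segmentation_metrics(result.final_mask, scene.ground_truth_mask, region=10)
print(f"accuracy={m.accuracy:.3f} precision={m.precision:.3f} "
      f"recall={m.recall:.3f} f1={m.f1:.3f}")
_, ndvi = compute_vi(scene, result.final_mask, "ndvi")
_, savi = compute_vi(scene, result.final_mask, "savi")
print(f"canopy NDVI={ndvi:.3f} SAVI={savi:.3f}")
print("energy history:", [round(e.E, 1) for e in result.energy_history])
```

prints

```
accuracy=1.000 precision=1.000 recall=1.000 f1=1.000
canopy NDVI=0.767 SAVI=0.652
energy history: [-93181.7, -98624.2]
```

The metrics are tiled: the image is split into 10×10-pixel sub-regions,
a confusion matrix is accumulated per tile (canopy = positive class) and
the four scores are macro-averaged over tiles. Here the shadowed upland
scene is still segmented perfectly; the energy history shows GrabCut
converging in two sweeps (E decreases, then α stops changing). The
canopy NDVI of 0.77 is what the biomass models consume.

The same workflow is available from the shell:

```bash
gfkuts simulate --per-stage 50 --seed 7 --out trial/
gfkuts segment  --scene trial/veg-0000/scene.yaml --l 1000 --radius 8 --seed 42 --out seg/
gfkuts features --trial trial/ --out features.csv
gfkuts train    --features features.csv --out model/
gfkuts evaluate --pred seg/final_mask.png --truth trial/veg-0000/truth_mask.png --region 10
```

Every subcommand writes a JSON run report with the fully resolved
configuration and seeds.

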