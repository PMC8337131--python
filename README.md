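# pisurf

Coarse-to-fine **p**rogressive-**i**mage **SURF** registration for 2-D
medical images (MR/MR and CT/MR brain slices and the like).

Feature-based registration with SURF often struggles when the floating
image F and the reference image R differ strongly: few feature matches
survive, many are wrong, and the estimated transform is poor.  `pisurf`
reduces that gap with *progressive images*: F and R are fused by
recursive pixel averaging,

    M_0 = (F + R) / 2,        M_{k+1} = (M_k + R) / 2,

which gives the closed form `M_l = 2^-(l+1) F + (1 - 2^-(l+1)) R` — a
chain of images that migrate from the mean of the pair toward R while
retaining a fading imprint of F.  Registration is then two-stage:

1. **coarse** — register F to the progressive image `M_l`
   (default `l = 7`) with the full SURF pipeline: integral image,
   box-filter Hessian scale space (filter sizes 9, 15, 21, 27; 15, 27,
   39, 51; ..., `sigma = 1.2 * size / 9`), strict 26-neighbour maxima
   with sub-pixel refinement, orientation assignment, 64-d descriptors,
   nearest/next-nearest-neighbour matching with a ratio test, and
   RANSAC + least-squares affine estimation;
2. **fine** — register the coarse result to R the same way; the two
   affines are composed and applied *once* to the original F with
   bicubic (Keys, a = -0.5) inverse-mapping resampling.

Alignment is scored with four classic similarity measures computed from
a joint intensity histogram: mutual information (MI), normalized mutual
information (NMI), normalized correlation coefficient (NCC) and mean
square difference (MSD).  Because public brain data cannot be shipped,
the package includes a deterministic phantom generator that produces
brain-slice-like images and misaligned pairs with *known* ground-truth
affines (optionally with a monotone intensity remap that emulates a
modality change), so geometric accuracy can be measured as a true target
registration error (TRE).

## Worked example

```python
import pisurf as ps

# a misaligned synthetic pair with known ground truth:
# 5 deg rotation about the centre, (7, -4) px translation
f, r, gt = ps.make_pair(ps.PhantomSpec(seed=7), rot=5, tx=7, ty=-4)

model = ps.ProgressiveRegistration(f, r, level=7)
res = model.fit(seed=1)
print(res.summary())
print("mean TRE (px): %.3f" % res.tre(gt.transform)[0])
```

prints

```
Progressive-image SURF registration results
===============================================
level used:        7
matches (coarse):  42
matches (fine):    53
seed:              1

 param     estimate    std err
-------------------------------
   r00     0.996750     0.0301
   r01    -0.087744     0.0341
    tx    15.232469     4.6566
   r10     0.086799     0.0389
   r11     0.995688     0.0440
    ty   -12.984104     6.0142

similarity vs reference
-------------------------------
MI  (bits):  3.9045
NMI:         1.7482
NCC:         0.9946
MSD:         0.000605

mean TRE (px): 0.049
```

The parameter block is the composed affine mapping floating coordinates
`(x', y')` to reference coordinates `(x, y)`; `r00..r11` is the linear
part (here: a ~5 degree rotation, `sin 5° ≈ 0.087`) and `tx, ty` the
translation in pixels, with standard errors propagated from the residuals
of the final correspondence set.  The metric block scores the warped
result against the reference; a mean TRE of 0.05 px on a 10x10 control
grid means the ground-truth misalignment was recovered to well under a
pixel.  `res.plot()` shows reference / warped / difference panels, and
`model.fit_sweep(max_level=9)` traces registration quality across
progressive levels.

The same functionality is exposed on the command line:

```sh
pisurf synth --out pair --seed 5 --rot 4 --tx 6 --ty -3
pisurf register pair/floating.png pair/reference.png --level 7 --out run
pisurf metrics pair/reference.png run/warped.png
pisurf sweep pair/floating.png pair/reference.png --max-level 9
```

`register` writes the warped image, the transform (6-number text file),
a JSON metric report and a reproducibility manifest; exit codes are 0 on
success, 1 on registration failure, 2 on usage errors.

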