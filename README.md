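# sasmorph

Quantitative morphometry of the optic-nerve subarachnoid space (ON SAS)
from 3D grayscale tomography, at desk scale.

The subarachnoid space around the human optic nerve is not an open
CSF-filled gap: it is spanned by a dense microstructure of trabeculae,
septa and pillars, lined by meningothelial cells. Two questions drive the
analysis this package implements: *how much of the SAS volume does the
microstructure occupy*, and *by what factor does it amplify the
CSF-facing surface area* compared to an empty sheath? Both matter for CSF
flow resistance and for the exchange surface available to meningothelial
cells, with downstream relevance to papilledema, normal-tension glaucoma
and spaceflight-associated neuro-ocular syndrome.

`sasmorph` reimplements the full image-analysis chain needed to answer
those questions from micro-CT-style data:

1. **tiling** — phase-correlation registration of overlapping tiles with
   sub-voxel parabolic refinement, least-squares reconciliation of
   pairwise shifts into global offsets, and seamless blending with
   jointly-fitted per-tile polynomial backgrounds and cosine feathering;
2. **enhance** — a curvelet-style Fourier filter bank (smooth dyadic
   radial octaves × raised-cosine angular wedges on the hemisphere,
   a partition of unity at unit gains) that removes smooth background
   fields and damps thin filamentous fixation artifacts;
3. **segment** — hard thresholding plus connected-component and
   morphological logic that separates three compartments: the optic nerve
   (ON), the SAS microstructure, and the CSF;
4. **geometry** — sub-voxel signed Euclidean distance fields φ, volume by
   a first-order mollified-step integral ∫ U_ε(φ) dΩ, and interface area
   from a marching-cubes triangle mesh of the φ = 0 level set;
5. **morphometry** — model-independent local thickness
   (Tb.Th-style): at every voxel, the diameter of the largest ball
   inscribed in the foreground that contains it; separation is the same
   measure on the CSF. Computed by an exact distance-ridge algorithm that
   matches a brute-force oracle voxel for voxel, plus volume-weighted
   thickness/separation density functions and a census of intertrabecular
   fluid spaces (watershed on the separation field);
6. **report** — Table-style summaries: CSF volume and interface area,
   measured and after *digitally removing* the microstructure, the
   surface amplification factor (measured area / microstructure-free
   area), the microstructure volume fraction, and angular renormalization
   360/(360 − θ) for a damaged sector discarded before measurement;
7. **phantom** — a seeded synthetic generator (cylindrical nerve, dura
   shell, capsule trabeculae, septa, partial-volume supersampling, noise,
   per-tile background gradients, thin bright artifacts) whose closed-form
   geometry gives every stage analytic ground truth.

## Worked example

Generate a noise-free phantom, segment it, and compile the morphometry
summary with a 60° damaged sector excluded and renormalized:

```python
from sasmorph import (PhantomSpec, generate_phantom, BinaryMask,
                      build_segments, compile_report, ReportConfig)

spec = PhantomSpec(rng_seed=0, noise_sigma=0.0)
volume, truth = generate_phantom(spec)
raw = BinaryMask(volume.data >= 0.5, voxel_size_um=spec.voxel_size_um)
segs = build_segments(raw, closing_radius_um=24.0,
                      macro_opening_radius_um=10.0,
                      exclude_boundary_csf=True)
rep = compile_report(segs, ReportConfig(sector_angle_deg=60.0))
```

which prints, via the snippet in `rep`'s fields:

```
CSF volume (measured / no microstructure): 814 / 882 x 10^-6 mm^3
interface area (measured / no microstructure): 0.0795 / 0.0656 mm^2
surface amplification factor: 1.21
microstructure volume fraction: 7.7%
angular renormalization factor: 1.20
```

Reading: the 12 default trabeculae occupy 7.7% of the SAS volume
(no-microstructure volume 882 vs measured 814 × 10⁻⁶ mm³) and raise the
CSF-facing interface area 1.21-fold over the counterfactual empty
annulus. On real bulbar and intraorbital nerve segments, the same
arithmetic applied to published measurements gives amplification factors
of 4.86 and 3.24 and volume fractions near 36% — a far denser meshwork
than any desk-scale phantom.

A thin CLI wraps the stages for shell use:

```bash
sasmorph phantom --out-dir run/ --seed 0 --tiles
sasmorph stitch run/tiles --out run/stitched.tif
sasmorph enhance run/stitched.tif --out run/enhanced.tif
sasmorph segment run/enhanced.tif --out-dir run/segments
sasmorph report run/segments --out run/report.json
```

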