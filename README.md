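# mitonode

Quantification of ER-associated mitochondrial fission/fusion biology from
multi-channel fluorescence microscopy, together with a synthetic-microscopy
generator that provides exact ground truth for every stage.

Mitochondrial fission and fusion initiate at **ER–mitochondria membrane
contact sites**: the ER wraps around a mitochondrion, the matrix narrows
(a *constriction*), and fission (Drp1) and fusion (Mfn1) machineries
assemble at shared spots called **nodes**. This package automates the
image-quantification readouts used to study that biology:

| readout | definition | module |
|---|---|---|
| mean area per mitochondrion | Otsu mask area in an ROI / particle count (µm²) | `morphology` |
| constriction fraction | crossings where the matrix signal dips ≥ 40% below the neighbouring peak, over resolvable ER crossings | `contacts` |
| Mander's overlap | \|A ∩ B\| / \|B\| of two binary masks (B = mitochondria) | `contacts` |
| Mfn1 density | persistent puncta per µm of skeleton length | `puncta` |
| Drp1 at crossings | % of resolvable ER crossings with a persistent Drp1 punctum | `puncta` |
| node density | one-to-one Drp1–Mfn1 punctum pairs per µm | `puncta` |
| fusion / fission rates | photoconversion-scored events per mitochondrion per minute, fusion binned tip-to-tip vs tip-to-middle | `dynamics` |
| group statistics | one-way ANOVA + Tukey HSD, two-tailed t, violin summaries, LFQ enrichment ranking | `stats` |

Because the live-cell acquisitions behind these readouts are not publicly
deposited, the `simulate` module is a first-class component: it builds
scenes of curvilinear mitochondria and ER tubules with programmed
constriction probabilities, puncta densities, and Poisson-scheduled
fission/fusion events (including photoconversion of a single mitochondrion
with label mixing), renders them with diffraction blur and Poisson +
Gaussian camera noise, and exports the exact ground truth. Every analysis
stage is validated against it.

## Worked example

```python
from mitonode import ROI, apply_photoconversion, build_scene, render_movie
from mitonode.dynamics import score_movie
from mitonode.simulate import SceneParams

scene = build_scene(SceneParams.photoconversion_movie(), seed=6)
pts = scene.filaments[0].points
mid = pts[len(pts) // 2]
scene = apply_photoconversion(
    scene, ROI(origin=(int(mid[0] / 0.1) - 10, int(mid[1] / 0.1) - 10),
               size=(2.0, 2.0)))
movie = render_movie(scene, seed=506)     # 61-frame, 5-s-interval stack
events, rates = score_movie(movie)
print(rates.fusion_rate, rates.tip_to_middle_rate, rates.fission_rate)
```

prints (for this seed)

```
fusion rate:  0.300 /mito/min (tip-to-middle 0.167, tip-to-tip 0.133; truth 0.300)
fission rate: 0.200 /mito/min (truth 0.200)
```

i.e. nine fusion and six fission events were detected across six
mitochondria over five minutes, each fusion confirmed by red
(photoconverted-channel) fluorescence mixing into a previously unlabelled
partner, and every detected rate equals the scene's ground truth. The
`examples/` directory has one short script per capability:

| script | shows |
|---|---|
| `01_simulate_and_render.py` | scene building, OME-TIFF rendering, ground-truth export |
| `02_morphology.py` | Otsu mask, particle counts, mean area, skeletonisation |
| `03_constrictions.py` | the ≥40% dip caller and crossing fraction |
| `04_puncta_and_nodes.py` | persistent-puncta densities and node scoring |
| `05_fusion_fission_rates.py` | photoconversion event scoring and rates |
| `06_stats_and_enrichment.py` | ANOVA/Tukey, violin summaries, LFQ ranking |

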