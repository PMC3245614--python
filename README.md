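# radialfish

Radial positioning analysis of chromosome territories in interphase nuclei
from two-channel fluorescence microscopy (DAPI + whole-chromosome paint
FISH).

Interphase chromosomes occupy preferred radial positions — gene-rich
chromosomes toward the nuclear interior, gene-poor ones toward the
periphery — and these positions shift when cells exit the cell cycle or in
laminopathies. `radialfish` implements the two standard quantifications of
that positioning for cell biologists working with FISH images of single
nuclei:

1. **2D erosion-shell analysis.** The DAPI-segmented nucleus is divided
   into five concentric shells of *equal area* (shell 1 = periphery,
   shell 5 = interior). For each nucleus the percentage of total
   chromosome-paint intensity in shell *k* is divided by the percentage of
   total DAPI intensity in that shell:

   `normalized_k = (probe_k / Σ probe) ÷ (dapi_k / Σ dapi)`

   so that 1 means "distributed like bulk DNA". Profiles are averaged over
   ≥ 50 nuclei per condition (mean ± SEM) and conditions are compared shell
   by shell with Welch's unpaired, unequal-variance, two-tailed *t*-test.

2. **3D distance to the nuclear periphery.** In confocal z-stacks
   (axial step 0.2 μm), chromosome territories are segmented in the paint
   channel and the distance from each territory's geometric center to the
   nearest voxel of the nuclear boundary is measured in μm under
   anisotropic voxel spacing — raw, and normalized by nucleus size
   (÷ (major + minor)/2 or ÷ major axis) — then summarized as frequency
   distribution curves per condition.

Because suitable raw microscopy is rarely shareable, the package includes a
synthetic scene generator that renders nuclei (perturbed ellipses /
ellipsoids) with territories placed at controlled radial preferences
(peripheral / intermediate / interior, or any Beta law) and records the
ground-truth radial coordinate of every territory, so the entire pipeline
is testable end to end.

## Worked example

Two synthetic cohorts of 50 nuclei — one with a peripheral territory
preference, one interior (the classic periphery↔interior repositioning
seen for chromosome 18 between proliferating and quiescent fibroblasts):

```python
import radialfish as rf
from radialfish.stats import comparisons_frame

def analyze(cfg, label):
    profiles = []
    for i in range(cfg.n_nuclei):
        img = rf.make_nucleus(cfg, i)
        mask = rf.segment_nucleus(img)
        profiles.append(rf.measure_shells(img, rf.build_shells(mask)))
    return rf.aggregate(profiles, label)

a = analyze(rf.SceneConfig(radial_law="peripheral", n_nuclei=50, seed=1), "peripheral-law")
b = analyze(rf.SceneConfig(radial_law="interior",   n_nuclei=50, seed=2), "interior-law")
print("mean profile A:", a.mean.round(2), "->", rf.classify_position(a))
print("mean profile B:", b.mean.round(2), "->", rf.classify_position(b))
print(comparisons_frame(rf.compare(a, b, alpha=0.05)).round(4).to_string(index=False))
```

prints

```
mean profile A: [1.64 1.64 1.08 0.44 0.2 ] -> peripheral
mean profile B: [0.19 0.33 0.75 1.59 2.12] -> interior
 shell        t      df  p_value  significant
     1  30.0930 57.8220      0.0         True
     2  41.8028 78.3485      0.0         True
     3   5.7753 81.1683      0.0         True
     4 -20.6997 74.9764      0.0         True
     5 -17.6075 49.1719      0.0         True
```

The peripheral-law cohort's signal is concentrated in shells 1–2 and the
interior-law cohort's in shells 4–5; every shell differs significantly
between the two conditions, with the sign of *t* flipping between the
peripheral and interior shells — a complete radial repositioning.

The same workflow is available from the shell:

```bash
radialfish simulate  --config scene.yaml --out cohort_a/
radialfish analyze2d --input cohort_a/ --out a/ --pixel-size 0.2
radialfish compare   --a a/shell_profiles.csv --b b/shell_profiles.csv --alpha 0.05 --out cmp/
radialfish analyze3d --input stacks/ --out out3d/ --pixel-size 0.1 --z-step 0.2
```

## Documentation

The model, parameter choices, numerical conventions and limitations are
described in [`docs/methods.md`](docs/methods.md).
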