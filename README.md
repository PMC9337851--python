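# mitopits

Quantitative image analysis of induced clathrin-coated pits ("MitoPits")
on mitochondrial networks — with a fully ground-truthed synthetic-scene
generator, so that every stage of the analysis can be exercised and
validated without any microscopy data.

Chemically induced recruitment of a clathrin-binding "hook" to a
mitochondrial "anchor" creates clathrin-coated pits on the mitochondrial
surface, which can bud into double-membraned vesicles. Three quantitative
questions drive the analysis this package implements:

1. **Where do pits form?** A mitochondrial network is a graph of tubular
   *edges* (radius r ≈ 250 nm) meeting at *branchpoints*, terminating at
   *endpoints*. Pits are counted per location class, but raw counts are
   confounded by surface area: modelling each edge as a cylinder
   (area `2πr·l`) and each endpoint as a hemispherical cap (`2πr²`), the
   area-corrected odds ratio is

       OR = [p/(1−p)] · [a_edge/a_end],

   where `p` is the endpoint share of endpoint+edge pits and `a_end`,
   `a_edge` are the class area fractions. The preference percentage is
   `100·OR/(1+OR)`, with χ² goodness-of-fit against either null.
2. **How are pits organized and sized?** Per-channel 1-D Gaussian fits to
   line profiles drawn across a pit give inter-channel peak offsets
   (matrix → membrane anchor → hook) and widths (FWHM = 2√(2 ln 2)·σ);
   vesicle cross-sections are aligned on the outer-membrane major axis
   and measured for outer diameter and intermembrane distance.
3. **Is budding energetically plausible?** The Helfrich bending density
   `G_bending = 8πκ/(4πr²) = 2κ/r²` plus membrane tension γ, applied per
   membrane, is compared with the ~0.08 k_BT nm⁻² that clathrin assembly
   can contribute.

The package also provides spot detection (band-pass + threshold +
area/circularity particle filter), organelle segmentation, free-spot
classification, greedy nearest-pair colocalization and spot density —
the operators a practitioner needs to take a multichannel TIFF to the
statistics above.

## Worked example

The numbered scripts under `analysis/` are thin drivers over the library
(`src/mitopits/`) and write their tables under `results/`. Running

```sh
python analysis/03_location_preference.py
```

prints, first, the desk arithmetic from the published proportions:

```
published-input arithmetic:
  uncorrected odds  p/(1-p)            = 2.66
  chi2 = 61.4, df = 1  ->  p           = 4.7e-15
  area-corrected odds ratio            = 47.5
  corrected endpoint preference        = 97.9%
```

i.e. 72.7% of pits at endpoints corresponds to 2.66:1 odds against a
50/50 null, and because endpoints carry only ~5.3% of the network's
surface area, the area-corrected preference for endpoints is 97.9%.
Second, a full synthetic round trip — ten scenes planted with endpoint
weight 47.5 and a 20% free fraction, pushed through detection,
segmentation, skeletonization, location assignment and the statistics:

```
synthetic round trip (planted endpoint weight 47.5):
  pooled counts                        = {'n_endpoint': 58, 'n_branchpoint': 0, 'n_edge': 12, 'n_free': 17}
  recovered corrected odds ratio       = 35.6  (95% bootstrap [19.8, 78.6])
  recovered free fraction              = 19.5%  (planted 20%)
```

The planted weight lies inside the bootstrap interval and the free
fraction comes back within half a point. The other scripts simulate and
inspect a single annotated scene (`01`, `02`), recover the planted
−80/−180 nm channel offsets and the 120 nm vesicle diameter (`04`), and
evaluate the budding energy budget (`05`), which prints a total cost of
0.0217 ≈ 0.022 k_BT nm⁻² for a double-membraned 60 nm vesicle — well
under the 0.08 k_BT nm⁻² clathrin budget.

## Layout

    analysis/           numbered narrative drivers (simulate → detect →
                        preference → geometry → energetics)
    src/mitopits/       the library: synthetic, detection, graph, stats,
                        profiles, energetics, pipeline, io
    tests/              pytest suite (unit, property and acceptance tests)
    docs/methods.md     models, parameter choices, numerical details
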