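# inkfidelity

Quantitative shape-fidelity and biocompatibility assessment for
extrusion-bioprinted alginate/gelatin constructs:

- **`inkfidelity.beam`** — tensioned simply-supported beam model of a
  filament hanging between supports (closed-form solution with the four
  simply-supported boundary conditions, a finite-difference BVP oracle,
  and the stable untensioned limit `5qL⁴/384EI`), plus inverse Young's
  modulus estimation by bisection and the modulus-vs-radius regression.
- **`inkfidelity.filament`** — image/time-series metrics of the filament
  collapse test: support deflection angles θ₁/θ₂, mid-span diameter,
  time-to-flat, diameter-shrink slope.
- **`inkfidelity.grid`** — pore segmentation of printed lattice scaffolds,
  matching to the designed 11 × 11 cell grid, normalized pore number and
  pore-area statistics.
- **`inkfidelity.viability`** — live/dead quantification from two-channel
  fluorescence z-stacks: per-channel max z-projection, prominence-based
  spot detection (ImageJ "find maxima" semantics, noise tolerance 20),
  per-image and pooled viability percentages.
- **`inkfidelity.fixtures`** — seed-deterministic synthetic inputs for all
  three pipelines with analytic ground truth.
- **`inkfidelity.stats`** — single-factor ANOVA and the paired two-sample
  t-test.

## CLI

```bash
# modulus estimation from a digitised angle/diameter time series
inkfidelity beamfit series.csv -P 5e-6 --gap 8 --out-dir results/

# filament series summary (time-to-flat, diameter slope)
inkfidelity filament series.csv --out-dir results/

# grid pore metrics for one or more top-view images
inkfidelity grid grid.png --span 20 --cells 11 --line-width 0.4

# live/dead viability for multi-page TIFF z-stacks (6 planes x 2 channels)
inkfidelity viability stack1.tif stack2.tif --out-dir results/

# synthetic fixtures with ground truth
inkfidelity simulate filament --modulus 10 --gaps 4,8 --out-dir fixtures/
inkfidelity simulate grid --merges 2 --out-dir fixtures/
inkfidelity simulate zstack --live 90 --dead 10 --out-dir fixtures/

# statistics on CSV columns
inkfidelity stats data.csv --test anova --columns g1,g2,g3
```

Boundary units are mm / degrees / kPa; SI is used internally. The axial
"transfer loading" `P` is not identifiable from a single filament and must
be supplied explicitly; every report records the value used.

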