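# vesiscope

Quantification of axonal vesicle-fusion hotspots, myelin profiles and sheath
growth from fluorescence time-lapse movies, exercised end-to-end on synthetic
scenes with known ground truth.

The pipeline:

1. **synthetic** — forward model: straight axon with collaterals, residual
   surface fluorescence (attenuated under myelin gaps), focal fusion events
   (Gaussian spots with plateau + exponential-tail kinetics), photobleaching,
   rigid drift, Poisson + Gaussian noise; plus a static reporter channel whose
   gaps mark sheaths, and sheath growth coupled to local event rates.
2. **preprocess** — exponential bleach-correction (whole-field fit), integer
   rigid registration (phase correlation), per-pixel dF/F_avg.
3. **detection** — candidate local maxima of dF/F_avg, ROI growth from the
   peak pixel (4-connected, ⅓ of max), acceptance when the ROI-mean trace
   exceeds 5 baseline SDs for ≥4 frames; amplitude (peak dF/F₀ in the first
   10 frames), duration (return to within 1 SD), per-frame displacement
   tracking with static / limited / excluded-mobile classes. An exhaustive
   brute-force oracle tests every pixel and frame against the same criteria.
4. **myelin** — reporter-profile segmentation into positive regions and gaps,
   heminodes (first 3 μm of positive axon bordering a gap), nodes (<1 μm
   between gaps), percent myelination, axon class.
5. **spatial** — compartment assignment, length/time-normalized frequencies,
   observed-vs-predicted heminodal enrichment with a paired signed-rank test,
   co-localization counts.
6. **sheaths** — landmark-based sheath matching across sessions, growth rates
   and fates, the 6 μm nascent-length contingency, growth-vs-activity
   correlations, fully-grown classification, frequency fold changes.
7. **calcium** — pre/post-treatment dF/F response analysis.
8. **stats / pipeline / cli** — normality-based test selection
   (D'Agostino-Pearson + Shapiro-Wilk routing to t/ANOVA vs
   Mann-Whitney/Wilcoxon/Kruskal-Wallis) and the orchestrated end-to-end run.

## CLI

A single `vesiscope` command with subcommands:

```sh
vesiscope simulate --seed 1 --out scene/          # movie + red channel + truth
vesiscope preprocess scene/movie.tif --pixel-size 0.25 --frame-interval 1.0 \
    --out pre/ --no-register
vesiscope detect pre/corrected.tif --geometry scene/geometry.json \
    --pixel-size 0.25 --frame-interval 1.0 --out events.csv
vesiscope profile scene/red.tif --geometry scene/geometry.json \
    --pixel-size 0.25 --out profile
vesiscope hotspots events.csv --profile profile.json \
    --geometry scene/geometry.json --duration-h 0.17 --out report.json
vesiscope run --seed 1 --out fullrun/              # everything end to end
```

Scene parameters are a JSON/YAML `SceneConfig` (`--config`); all randomness is
controlled by `--seed`.

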