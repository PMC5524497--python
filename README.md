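# camotype

Which sample of a variable background is the best camouflage?

Most natural backgrounds — tree bark, leaf litter, gravel — vary
continuously in colour and texture, so a prey animal cannot match all of
them at once.  `camotype` implements the analysis behind a simple
prediction: the best single camouflage is the **most probable background
sample**, the one closest to the centre of the background's feature
distribution at the spatial scale of the prey.  The package is aimed at
researchers in sensory ecology and visual psychophysics who want to
quantify background typicality from images and test its effect on
detectability.

## What it does

For a background with discrete variants at probabilities `p_i`, a prey
that is a random sample of the background matches its patch with
probability `Σ p_i²`, while matching the most common variant succeeds with
probability `max p_i ≥ Σ p_i²` — so typicality beats random sampling.  For
continuous variation the analogue of the most common variant is the point
minimizing expected deviation cost: the centroid (arithmetic mean, the
Gaussian ML location) under squared-Euclidean cost, the coordinate-wise
median under absolute cost.

The pipeline turns that idea into a testable experiment:

1. **`synth`** — generate a synthetic bark-like background population with
   known tree-level colours and octave-band texture spectra (stands in for
   photographs, providing ground truth);
2. **`calibrate`** — linearize and white-balance camera images against an
   embedded colour standard, optionally mapping to a receptor space;
3. **`features`** — sample five non-overlapping prey-sized patches
   (591 × 296 px = 5 × 2.5 cm at 300 dpi) per image and extract colour
   means and granularity spectra;
4. **`typicality`** — fit the feature distribution, rank every sample by
   Euclidean distance from the colour and texture centroids (with a
   kernel-density cross-check), and select the 2 × 2 common/rare stimulus
   sets (12 targets per treatment);
5. **`design`** — build the 10-block field placement schedule and the
   48 × 48 Williams Latin-square visual-search schedule (2304 stimuli,
   each target on each background exactly once);
6. **`simulate`** — generate survival and search outcomes whose
   detectability depends on distance from the centroid;
7. **`stats`** — mixed-effects Cox regression with target and block
   frailties and change-in-deviance χ² tests for the field data; linear
   and binomial mixed models on z-scored distances for the search data.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

```python
import numpy as np
from camotype import synth, typicality, stats
from camotype.features import extract_features
from camotype.design import build_field_schedule
from camotype.simulate import DetectionModel, simulate_field
from camotype.typicality import ranks_to_frame

params = synth.PopulationParams(seed=7)
features = []
for tree_id in range(101):                       # stream the population
    image = synth.generate_tree_image(params, tree_id)
    features += extract_features([image], n_patches=5, seed=8 + tree_id)
print(len(features))                             # 505 feature vectors

fit = typicality.fit_ml(features)
ranked = typicality.distances(fit, features)
selection = typicality.select_treatments(ranked, n_per_treatment=12)
print({t: len(g) for t, g in selection.groups.items()})
# {'Col+Txt+': 12, 'Col+Txt-': 12, 'Col-Txt+': 12, 'Col-Txt-': 12}

schedule = build_field_schedule(selection, n_blocks=10, seed=1)
records = simulate_field(schedule, ranks_to_frame(ranked),
                         DetectionModel(), seed=2)
full = stats.fit_field_model(records, include_interaction=True)
reduced = stats.fit_field_model(records, include_interaction=False)
res = stats.lr_deviance_test(full, reduced)
print(f"interaction: chi2 = {res.statistic:.2f}, p = {res.p_value:.4f}")
# interaction: chi2 = 23.49, p = 0.0000
for label, t in stats.split_by_colour_and_test_texture(records).items():
    print(f"texture within {label}: chi2 = {t.statistic:.2f}, p = {t.p_value:.4f}")
# texture within Col+: chi2 = 33.82, p = 0.0000
# texture within Col-: chi2 = 0.06, p = 0.8091
```

The interaction says colour and texture matching are non-additive: the
stratified tests show texture typicality only improves survival when the
target's colour is already common in the background — targets rare in
colour are found regardless of their texture.

The same stages are available from the shell:

```bash
camotype synth --n-trees 101 --seed 7 --out raw/
camotype calibrate --chart raw/colour_standard.csv \
    --chart-image raw/colour_standard.png --in raw/ --out cal/
camotype features --in cal/ --patches 5 --dims 591x296 --seed 8 --out features.csv
camotype select --features features.csv --per-treatment 12 --out-dir sel/
camotype design field --selection sel/selection.csv --seed 1 --out field.csv
camotype simulate field --schedule field.csv --ranks sel/ranks.csv --seed 2 --out records.csv
camotype stats field --records records.csv --out results/
```

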