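"""Fit the extract-then-pool habitat model and check the selected K.

Voxel-level sliding-window features are pooled within SLIC supervoxels and
clustered across the training split; the silhouette coefficient selects the
number of habitats.
"""

import warnings

from habitat_radiomics import SyntheticConfig, generate_cohort
from habitat_radiomics.habitats import build_habitat_maps
from habitat_radiomics.preprocess import preprocess_study

warnings.simplefilter("ignore")

config = SyntheticConfig(
    n_patients=10,
    grid_shape=(40, 40, 40),
    # switch the class-dependent modulation off so every tumor carries the
    # same three pure signatures - the cleanest K-recovery setting
    alnm_habitat_effect={"dce_mean_shift": 0.0, "noise_scale": 1.0},
    seed=1,
)
cohort = generate_cohort(config)
cohort.studies = [preprocess_study(s) for s in cohort.studies]

model, maps, svsets = build_habitat_maps(cohort, seed=0, mm3_per_supervoxel=150.0)

print(f"selected K = {model.K} (3 habitats were planted)")
print("silhouette by k:", {k: round(v, 3) for k, v in model.silhouette_by_k.items()})
print(f"ordering rule: {model.ordering_rule}")
print("per-habitat mean DCE (ascending):",
      [round(s, 2) for s in model.ordering_statistic])
pid = cohort.studies[0].patient_id
print(f"\n{pid}: habitat voxel counts {maps[pid].counts}")
# Habitat 1 is the least-enhancing (necrotic reading) region and habitat K
# the most-enhancing (vascularized) one, consistently across patients.
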