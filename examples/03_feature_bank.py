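"""Extract the radiomics feature bank from one synthetic patient.

The bank computes 1,037 features per (sequence, region): 14 shape
descriptors plus 93 intensity/texture features on each of 11 images
(original, 8 wavelet subbands, 2 LoG scales). Across 3 sequences this gives
3,111 whole-tumor features and, with K = 3 habitats, 9,333 habitat features
(12,444 fused).
"""

from habitat_radiomics import SyntheticConfig, generate_cohort
from habitat_radiomics.features import (
    FeatureBankConfig,
    count_features,
    extract_study_features,
)

config = FeatureBankConfig()
print(f"features per (sequence, region): {count_features(config)}")

cohort = generate_cohort(SyntheticConfig(n_patients=4, grid_shape=(32, 32, 32), seed=2))
study = cohort.studies[0]
sequences = {name: vol for name, (vol, _) in study.sequences.items()}
features = extract_study_features(
    sequences,
    (1.0, 1.0, 1.0),
    study.tumor_mask,
    study.truth["habitat_map"],
    3,
    config,
)

conventional = [n for n in features if "_habitat" not in n]
habitat = [n for n in features if "_habitat" in n]
print(f"whole-tumor features: {len(conventional)}")
print(f"habitat features:     {len(habitat)}")
print(f"fusion total:         {len(features)}")

print("\na few values:")
for name in (
    "DCE_original_firstorder_Mean",
    "DCE_habitat3_original_firstorder_Mean",
    "T2WI_original_glcm_Contrast",
    "DWI_wavelet-LLL_glszm_ZoneEntropy",
    "DCE_original_shape_Sphericity",
):
    print(f"  {name:48s} {features[name]: .4f}")
# The habitat-3 DCE mean sits well above the whole-tumor mean: habitat 3 is
# the strongly enhancing subregion by construction of the ordering rule.
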