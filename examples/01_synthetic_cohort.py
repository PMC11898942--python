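"""Generate a matched multimodal cohort and inspect its planted structure.

The generator emulates the shape of a prostate-cancer biomarker study:
log2-scale miRNA expression with a few differential markers, T2W/ADC
lesion volumes whose texture differs by Gleason class, clinical
covariates, and per-sample Gleason labels shared across modalities.
"""

from mmdiscover import CohortSpec, gen_matched_cohort

spec = CohortSpec(n_indolent=7, n_significant=6, seed=42)
cohort = gen_matched_cohort(spec)

print(f"samples: {cohort.mirna.n_samples} (matched across all modalities)")
print(f"miRNA features: {cohort.mirna.n_features}")
print(f"informative miRNAs planted: {cohort.truth.informative_feature_ids}")
print(f"duplicate blocks planted: {len(cohort.truth.duplicate_groups)}")
print(f"clinical columns: {cohort.clinical.feature_ids}")
print("gleason labels:", dict(cohort.labels.gleason.head(4)))
img, mask = cohort.t2w_volumes[cohort.mirna.sample_ids[0]]
print(f"first T2W volume: shape {img.voxels.shape}, lesion {mask.n_voxels} voxels")
# The informative miRNA ids and duplicate groups are the ground truth that
# downstream recovery and redundancy tests check against.
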