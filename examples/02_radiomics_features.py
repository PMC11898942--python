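"""Extract the radiomic feature panel from one lesion volume.

Shows the named panel (first-order intensity, GLCM/GLSZM/GLRLM texture,
Laws energies, Haar wavelet sub-band energies, MVEE shape density and
weighted centre of mass) for a synthetic lesion of each Gleason class.
"""

from mmdiscover import CohortSpec, extract_feature_vector, gen_lesion_volume

spec = CohortSpec(seed=7, texture_contrast=1.5)
for klass in ("indolent", "significant"):
    image, mask = gen_lesion_volume(spec, klass, sample_index=0)
    fv = extract_feature_vector(image, mask)
    print(f"--- {klass} lesion ({mask.n_voxels} voxels) ---")
    for name in (
        "Statistical_Coefficient_of_variance",
        "Avg_Coocurrence_Joint_MAX",
        "avgCoocurrence_Difference_entropy",
        "GLSZM_High_grey_level_zone_emphasis",
        "Volume_density_minimum_volume_enclosing_ellipsoid",
        "3D_Laws_features_L5_E5_S5",
        "3D_Wavelet_P1_L2_C12",
    ):
        print(f"  {name:55s} {fv[name]:.4f}")
print(f"full panel size: {len(fv)} named features")
# The significant class is generated with a longer noise correlation
# length, so its co-occurrence features (e.g. joint maximum up, difference
# entropy down) separate from the indolent class.
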