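"""Catalogue of the 99 radiomic features computed per tumour scan.

The catalogue fixes the feature names, their family membership and the
canonical report order.  Four families are distinguished:

* ``first``   -- 37 first-order (histogram) features: 20 computed on
  decay-corrected activity-concentration values ("ROI" features) plus the
  metabolic volume pair, and 17 on SUV-converted values.
* ``second``  -- 25 second-order features: 21 grey-level co-occurrence
  (GLCM) features and 4 grey-level difference (GLDM) features.
* ``high``    -- 31 high-order features: 13 run-length (GLRL), 13 size-zone
  (GLSZM) and 5 neighbourhood grey-tone difference (NGTDM) features.
* ``fractal`` -- 6 model-based features from differential box counting,
  gliding-box lacunarity, the blanket method and the variogram Hurst
  exponent.
"""

from __future__ import annotations

FIRST_ORDER_FEATURES: tuple[str, ...] = (
    "roi_mean",
    "roi_maximum",
    "roi_minimum",
    "roi_range",
    "roi_standard_deviation",
    "roi_skewness",
    "roi_kurtosis",
    "roi_coefficient_of_variation",
    "roi_median",
    "roi_10th_percentile",
    "roi_25th_percentile",
    "roi_75th_percentile",
    "roi_90th_percentile",
    "roi_entropy",
    "roi_energy",
    "roi_log_entropy_1_5",
    "roi_log_entropy_2_0",
    "roi_log_entropy_2_5",
    "metabolic_active_volume_cm3",
    "effective_diameter_cm",
    "suv_mean",
    "suv_total_lesion_glycolysis",
    "suv_peak",
    "suv_maximum",
    "suv_minimum",
    "suv_range",
    "suv_standard_deviation",
    "suv_skewness",
    "suv_kurtosis",
    "suv_coefficient_of_variation",
    "suv_median",
    "suv_10th_percentile",
    "suv_25th_percentile",
    "suv_75th_percentile",
    "suv_90th_percentile",
    "suv_entropy",
    "suv_energy",
)

GLCM_FEATURES: tuple[str, ...] = (
    "glcm_autocorrelation",
    "glcm_cluster_prominence",
    "glcm_cluster_shade",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_difference_entropy",
    "glcm_difference_variance",
    "glcm_dissimilarity",
    "glcm_energy",
    "glcm_entropy",
    "glcm_homogeneity",
    "glcm_information_measure_correlation_1",
    "glcm_information_measure_correlation_2",
    "glcm_inverse_difference_moment",
    "glcm_inverse_difference_moment_normalised",
    "glcm_inverse_difference_normalised",
    "glcm_maximum_probability",
    "glcm_sum_average",
    "glcm_sum_entropy",
    "glcm_sum_of_squares_variance",
    "glcm_sum_variance",
)

GLDM_FEATURES: tuple[str, ...] = (
    "gldm_mean",
    "gldm_entropy",
    "gldm_variance",
    "gldm_contrast",
)

SECOND_ORDER_FEATURES: tuple[str, ...] = GLCM_FEATURES + GLDM_FEATURES

GLRL_FEATURES: tuple[str, ...] = (
    "glrl_short_run_emphasis",
    "glrl_long_run_emphasis",
    "glrl_grey_level_nonuniformity",
    "glrl_run_length_nonuniformity",
    "glrl_run_percentage",
    "glrl_low_grey_level_run_emphasis",
    "glrl_high_grey_level_run_emphasis",
    "glrl_short_run_low_grey_level_emphasis",
    "glrl_short_run_high_grey_level_emphasis",
    "glrl_long_run_low_grey_level_emphasis",
    "glrl_long_run_high_grey_level_emphasis",
    "glrl_intensity_variability",
    "glrl_run_length_variability",
)

GLSZM_FEATURES: tuple[str, ...] = (
    "glszm_short_zone_emphasis",
    "glszm_long_zone_emphasis",
    "glszm_intensity_nonuniformity",
    "glszm_zone_length_nonuniformity",
    "glszm_zone_percentage",
    "glszm_low_intensity_zone_emphasis",
    "glszm_high_intensity_zone_emphasis",
    "glszm_short_zone_low_intensity_emphasis",
    "glszm_short_zone_high_intensity_emphasis",
    "glszm_long_zone_low_intensity_emphasis",
    "glszm_long_zone_high_intensity_emphasis",
    "glszm_intensity_variability",
    "glszm_size_zone_variability",
)

NGTDM_FEATURES: tuple[str, ...] = (
    "ngtdm_coarseness",
    "ngtdm_contrast",
    "ngtdm_busyness",
    "ngtdm_complexity",
    "ngtdm_texture_strength",
)

HIGH_ORDER_FEATURES: tuple[str, ...] = GLRL_FEATURES + GLSZM_FEATURES + NGTDM_FEATURES

FRACTAL_FEATURES: tuple[str, ...] = (
    "fd_mean",
    "fd_sd",
    "fd_lacunarity",
    "fd_hurst_exponent",
    "fd_blanket_mean",
    "fd_inverse",
)

ALL_FEATURES: tuple[str, ...] = (
    FIRST_ORDER_FEATURES
    + SECOND_ORDER_FEATURES
    + HIGH_ORDER_FEATURES
    + FRACTAL_FEATURES
)

FAMILIES: tuple[str, ...] = ("first", "second", "high", "fractal")

FAMILY_OF: dict[str, str] = {}
for _name in FIRST_ORDER_FEATURES:
    FAMILY_OF[_name] = "first"
for _name in SECOND_ORDER_FEATURES:
    FAMILY_OF[_name] = "second"
for _name in HIGH_ORDER_FEATURES:
    FAMILY_OF[_name] = "high"
for _name in FRACTAL_FEATURES:
    FAMILY_OF[_name] = "fractal"
del _name

FAMILY_SIZES: dict[str, int] = {
    "first": len(FIRST_ORDER_FEATURES),
    "second": len(SECOND_ORDER_FEATURES),
    "high": len(HIGH_ORDER_FEATURES),
    "fractal": len(FRACTAL_FEATURES),
}

assert len(ALL_FEATURES) == 99
assert FAMILY_SIZES == {"first": 37, "second": 25, "high": 31, "fractal": 6}
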