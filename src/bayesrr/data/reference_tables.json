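{
  "description": "Published aggregate tables from the VIP1/VIP2/COVIP registry reanalysis of 30-day ICU mortality in nonagenarians (>=90 y) vs octogenarians (80-89 y). Group-level characteristics (counts, prevalences, median/IQR) and the published unadjusted (Model-1) Bayesian posterior summaries. Individual-level registry data are not public; these aggregates are the reproducible inputs.",
  "groups": {
    "octogenarian": {
      "n": 7601,
      "deaths_30d": 3219,
      "age_median_iqr": [83, 81, 86],
      "sofa_median_iqr": [7, 4, 10],
      "cfs_median_iqr": [4, 3, 6],
      "male": 0.55,
      "niv": 0.25,
      "mech_vent": 0.53,
      "vasoactive": 0.59,
      "rrt": 0.12,
      "withhold": 0.29,
      "withdraw": 0.16
    },
    "nonagenarian": {
      "n": 807,
      "deaths_30d": 365,
      "age_median_iqr": [91, 90, 93],
      "sofa_median_iqr": [6, 4, 9],
      "cfs_median_iqr": [5, 4, 6],
      "male": 0.43,
      "niv": 0.21,
      "mech_vent": 0.42,
      "vasoactive": 0.52,
      "rrt": 0.04,
      "withhold": 0.36,
      "withdraw": 0.13
    }
  },
  "published_model1_posterior": {
    "non_informative": {
      "hpd_low_rr": 0.946,
      "hpd_high_rr": 1.177,
      "p_gt_1_0": 0.882,
      "p_gt_1_1": 0.290,
      "p_gt_1_2": 0.018
    },
    "pessimistic": {
      "hpd_low_rr": 0.999,
      "hpd_high_rr": 1.163,
      "p_gt_1_0": 0.979,
      "p_gt_1_1": 0.347,
      "p_gt_1_2": 0.005
    },
    "skeptical": {
      "hpd_low_rr": 0.953,
      "hpd_high_rr": 1.119,
      "p_gt_1_0": 0.811,
      "p_gt_1_1": 0.070,
      "p_gt_1_2": 0.000
    }
  }
}
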