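schema_version: 1
population:
  n: 1259
  seed: 0
  tumor_probs:
    breast: 0.07
    colon: 0.01
    endometrial: 0.07
    gastric: 0.01
    hepatic: 0.01
    lung: 0.48
    ovarian: 0.28
    pancreatic: 0.04
    sarcoma: 0.03
  sex_given_tumor:
    breast: 0.0
    colon: 0.5454545454545454
    endometrial: 0.0
    gastric: 0.7142857142857143
    hepatic: 0.5625
    lung: 0.5930635838150289
    ovarian: 0.0
    pancreatic: 0.6515151515151515
    sarcoma: 0.4714285714285714
  origin_probs:
    European: 0.96
    Sub-Saharan African: 0.02
    East Asian: 0.02
  ecog_probs:
    0: 0.36842105263157887
    1: 0.5789473684210527
    2: 0.05263157894736842
  age_targets:
    male_nonsarcoma:
      mean: 62.3
      sd: 9.3
    male_sarcoma:
      mean: 62.3
      sd: 9.3
    female_nonsarcoma:
      mean: 59.1
      sd: 11.2
    female_sarcoma:
      mean: 59.1
      sd: 11.2
  age_bounds:
  - 18.0
  - 95.0
network:
  htc_log_scale: false
  equations:
  - id: 1
    response: height_cm
    response_scale: linear
    intercept: 179.9
    terms:
    - covariate: age_years
      scale: linear
      level: null
      coefficient: -0.16
    - covariate: sex
      scale: indicator
      level: female
      coefficient: -12.81
    - covariate: origin
      scale: indicator
      level: Sub-Saharan African
      coefficient: 6.42
    - covariate: origin
      scale: indicator
      level: European
      coefficient: 3.83
    interactions: []
  - id: 2
    response: weight_kg
    response_scale: log
    intercept: 2.1
    terms:
    - covariate: height_cm
      scale: linear
      level: null
      coefficient: 0.012
    - covariate: sex
      scale: indicator
      level: female
      coefficient: 0.562
    - covariate: origin
      scale: indicator
      level: Sub-Saharan African
      coefficient: 0.262
    - covariate: origin
      scale: indicator
      level: European
      coefficient: 0.144
    interactions:
    - covariate: height_cm
      scale: linear
      by: sex
      level: female
      coefficient: -0.004
  - id: 3
    response: aag_mg_dl
    response_scale: log
    intercept: 4.32
    terms:
    - covariate: ecog
      scale: indicator
      level: 1
      coefficient: 0.161
    - covariate: ecog
      scale: indicator
      level: 2
      coefficient: 0.449
    - covariate: origin
      scale: indicator
      level: Sub-Saharan African
      coefficient: 0.634
    - covariate: origin
      scale: indicator
      level: European
      coefficient: 0.37
    - covariate: tumor
      scale: indicator
      level: ovarian
      coefficient: 0.622
    interactions: []
  - id: 4
    response: albumin_g_dl
    response_scale: linear
    intercept: 5.546
    terms:
    - covariate: age_years
      scale: linear
      level: null
      coefficient: -0.004
    - covariate: aag_mg_dl
      scale: log
      level: null
      coefficient: -0.292
    - covariate: ecog
      scale: indicator
      level: 1
      coefficient: -0.128
    - covariate: ecog
      scale: indicator
      level: 2
      coefficient: -0.429
    - covariate: origin
      scale: indicator
      level: Sub-Saharan African
      coefficient: 0.276
    - covariate: origin
      scale: indicator
      level: European
      coefficient: 0.248
    - covariate: tumor
      scale: indicator
      level:
      - pancreatic
      - hepatic
      - gastric
      coefficient: -0.339
    interactions: []
  - id: 5
    response: hb_g_dl
    response_scale: linear
    intercept: 12.35
    terms:
    - covariate: albumin_g_dl
      scale: linear
      level: null
      coefficient: 0.575
    - covariate: aag_mg_dl
      scale: log
      level: null
      coefficient: -0.793
    - covariate: sex
      scale: indicator
      level: female
      coefficient: -0.68
    interactions: []
  - id: 6
    response: nl_ratio
    response_scale: log
    intercept: 1.47
    terms:
    - covariate: aag_mg_dl
      scale: log
      level: null
      coefficient: -0.0073
    - covariate: albumin_g_dl
      scale: linear
      level: null
      coefficient: -0.16
    interactions: []
  - id: 7
    response: pl_ratio
    response_scale: log
    intercept: 5.52
    terms:
    - covariate: hb_g_dl
      scale: linear
      level: null
      coefficient: -0.057
    - covariate: aag_mg_dl
      scale: linear
      level: null
      coefficient: 0.0016
    - covariate: nl_ratio
      scale: linear
      level: null
      coefficient: 0.0622
    - covariate: tumor
      scale: indicator
      level:
      - pancreatic
      - hepatic
      - gastric
      coefficient: -0.204
    interactions: []
  - id: 8
    response: crp_mg_l
    response_scale: log
    intercept: 1.394
    terms:
    - covariate: pl_ratio
      scale: linear
      level: null
      coefficient: 0.002
    - covariate: ecog
      scale: indicator
      level: 1
      coefficient: 0.368
    - covariate: ecog
      scale: indicator
      level: 2
      coefficient: 0.598
    - covariate: tumor
      scale: indicator
      level: breast
      coefficient: -2.22
    interactions: []
  - id: 9
    response: ldh_u_l
    response_scale: log
    intercept: 5.709
    terms:
    - covariate: crp_mg_l
      scale: linear
      level: null
      coefficient: 0.001
    interactions: []
  - id: 10
    response: htc_pct
    response_scale: linear
    intercept: 5.93
    terms:
    - covariate: aag_mg_dl
      scale: log
      level: null
      coefficient: 0.04
    - covariate: hb_g_dl
      scale: linear
      level: null
      coefficient: 2.515
    interactions: []
residuals:
  height_cm:
    sd: 4.0
    policy: resample
    bounds:
    - 0.0
    - .inf
  weight_kg:
    sd: 0.1
    policy: resample
    bounds:
    - 0.0
    - .inf
  aag_mg_dl:
    sd: 0.1
    policy: resample
    bounds:
    - 0.0
    - .inf
  albumin_g_dl:
    sd: 0.3
    policy: resample
    bounds:
    - 1.0
    - 6.0
  hb_g_dl:
    sd: 1.0
    policy: resample
    bounds:
    - 5.0
    - 20.0
  nl_ratio:
    sd: 0.1
    policy: resample
    bounds:
    - 0.0
    - .inf
  pl_ratio:
    sd: 0.1
    policy: resample
    bounds:
    - 0.0
    - .inf
  crp_mg_l:
    sd: 0.1
    policy: resample
    bounds:
    - 0.0
    - .inf
  ldh_u_l:
    sd: 0.1
    policy: resample
    bounds:
    - 0.0
    - .inf
  htc_pct:
    sd: 3.0
    policy: resample
    bounds:
    - 15.0
    - 60.0
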