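funnel:
  n_screened: 823600
  p_ldct_positive: 0.273
  p_nodule_in_range: 0.6163
test:
  prevalence: 0.0458
  sensitivity: 0.82
  specificity: 0.88
groups:
- group: SPN
  p_biopsy_year: 0.0615
  mean_procedure_count: 1.43
  p_biopsy_type:
    CT-guided biopsy: 0.1932
    bronchoscopy: 0.6914
    surgical biopsy: 0.1155
  p_procedure:
    chest imaging: 0.618
    PET/CT: 0.0062
  expected_assessment_cost:
    medicare: 514.95
    private: 1299.07
  cost_scale: 1.0
- group: LCDx
  p_biopsy_year: 0.8289
  mean_procedure_count: 1.18
  p_biopsy_type:
    CT-guided biopsy: 0.4275
    bronchoscopy: 0.4833
    surgical biopsy: 0.0892
  p_procedure:
    chest imaging: 0.7253
    PET/CT: 0.0134
  expected_assessment_cost:
    medicare: 3730.66
    private: 9048.67
  cost_scale: 1.0
lcdx_weight: 0.3263
perspectives:
- name: medicare
  price_multiplier: 1.0
  test_price: 760.0
- name: private
  price_multiplier: 2.64
  test_price: 760.0
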