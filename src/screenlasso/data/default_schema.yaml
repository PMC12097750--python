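# Default variable schema: four PCQ outcome scales and the 24 candidate
# predictors entering the bootstrapped LASSO models. Ranges are the
# admissible instrument ranges; `source` names the instrument.
variables:
  # ---- outcomes ----
  - {name: pcq_total,        vtype: ordinal,    lo: 0,  hi: 36,  role: outcome,   source: "PCQ negative (overall)"}
  - {name: pcq_emotional,    vtype: ordinal,    lo: 0,  hi: 15,  role: outcome,   source: "PCQ negative (emotional dysfunction)"}
  - {name: pcq_physical,     vtype: ordinal,    lo: 0,  hi: 12,  role: outcome,   source: "PCQ negative (physical dysfunction)"}
  - {name: pcq_social,       vtype: ordinal,    lo: 0,  hi: 9,   role: outcome,   source: "PCQ negative (social dysfunction)"}
  # ---- predictors ----
  - {name: koko_critical,    vtype: continuous, lo: 0,  hi: 100, role: predictor, source: "KoKo: critical and participatory communication index"}
  - {name: koko_active,      vtype: continuous, lo: 0,  hi: 100, role: predictor, source: "KoKo: active and disease-specific communication index"}
  - {name: help_apply,       vtype: continuous, lo: 1,  hi: 5,   role: predictor, source: "HELP: difficulties applying medical information"}
  - {name: help_interact,    vtype: continuous, lo: 1,  hi: 5,   role: predictor, source: "HELP: difficulties interacting with medical staff"}
  - {name: komo_count,       vtype: ordinal,    lo: 0,  hi: 12,  role: predictor, source: "KOMO: number of comorbidities"}
  - {name: komo_severity,    vtype: continuous, lo: 0,  hi: 10,  role: predictor, source: "KOMO: standardized severity score"}
  - {name: zap_trust,        vtype: ordinal,    lo: 1,  hi: 4,   role: predictor, source: "ZAP item: trust in general practitioner"}
  - {name: zap_quality,      vtype: ordinal,    lo: 1,  hi: 4,   role: predictor, source: "ZAP item: quality of treatment"}
  - {name: zap_satisfaction, vtype: ordinal,    lo: 1,  hi: 4,   role: predictor, source: "ZAP item: satisfaction with general practitioner"}
  - {name: osss,             vtype: ordinal,    lo: 1,  hi: 3,   role: predictor, source: "OSSS-3: social support index"}
  - {name: macarthur,        vtype: ordinal,    lo: 1,  hi: 10,  role: predictor, source: "MacArthur Scale: subjective social status"}
  - {name: screen_positive,  vtype: binary,     lo: 0,  hi: 1,   role: predictor, source: "administrative: screening outcome positive"}
  - {name: info_procedure,   vtype: ordinal,    lo: 1,  hi: 5,   role: predictor, source: "self-developed: satisfaction with information on screening procedure"}
  - {name: info_risk,        vtype: ordinal,    lo: 1,  hi: 5,   role: predictor, source: "self-developed: satisfaction with information on risk factors"}
  - {name: good_hands,       vtype: ordinal,    lo: 1,  hi: 5,   role: predictor, source: "self-developed: feeling of being in good hands (GP)"}
  - {name: household_size,   vtype: ordinal,    lo: 1,  hi: 7,   role: predictor, source: "ISSP single item: household size (persons)"}
  - {name: school_degree,    vtype: ordinal,    lo: 1,  hi: 5,   role: predictor, source: "ISSP single item: school degree"}
  - {name: prof_training,    vtype: ordinal,    lo: 1,  hi: 4,   role: predictor, source: "ISSP single item: professional training"}
  - {name: employed,         vtype: binary,     lo: 0,  hi: 1,   role: predictor, source: "ISSP single item: occupational status (recoded)"}
  - {name: partner,          vtype: binary,     lo: 0,  hi: 1,   role: predictor, source: "ISSP single item: existence of a life partner"}
  - {name: received_result,  vtype: binary,     lo: 0,  hi: 1,   role: predictor, source: "self-developed: received information of test result"}
  - {name: future_screening, vtype: binary,     lo: 0,  hi: 1,   role: predictor, source: "self-developed: future participation in liver screening"}
  - {name: sex,              vtype: binary,     lo: 0,  hi: 1,   role: predictor, source: "ISSP single item: sex (1 = female)"}
  - {name: age,              vtype: continuous, lo: 31, hi: 98,  role: predictor, source: "ISSP single item: age (years)"}
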