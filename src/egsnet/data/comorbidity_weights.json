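{
  "_comment": "Synthetic, replaceable comorbidity-grouper fixture: category weights in the style of van Walraven-type Elixhauser summary weights, with a small illustrative code map. Users of real claims data should substitute a full licensed/published grouper with the same JSON shape.",
  "categories": {
    "congestive_heart_failure": {"weight": 7, "codes": ["I50", "I509", "I5022"]},
    "cardiac_arrhythmia": {"weight": 5, "codes": ["I480", "I4891", "I499"]},
    "pulmonary_circulation_disorder": {"weight": 4, "codes": ["I270", "I2720"]},
    "chronic_pulmonary_disease": {"weight": 3, "codes": ["J449", "J441", "J45909"]},
    "renal_failure": {"weight": 5, "codes": ["N183", "N184", "N185"]},
    "liver_disease": {"weight": 11, "codes": ["K7030", "K743", "K7460"]},
    "metastatic_cancer": {"weight": 12, "codes": ["C7800", "C787", "C792"]},
    "coagulopathy": {"weight": 3, "codes": ["D65", "D684", "D689"]},
    "weight_loss": {"weight": 6, "codes": ["E41", "E43", "R634"]},
    "fluid_electrolyte_disorder": {"weight": 5, "codes": ["E861", "E870", "E872"]},
    "obesity": {"weight": -4, "codes": ["E6601", "E669"]},
    "depression": {"weight": -3, "codes": ["F329", "F330"]}
  }
}
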