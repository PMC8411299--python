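{
  "_comment": "Synthetic, replaceable code-set fixture. The diagnosis/procedure lists below are a small illustrative stand-in for the licensed AAST EGS diagnosis list, the published complication lists, and the HCUP Surgery Flags procedure lists, which must be supplied by the user for real analyses. Codes are ICD-10-CM / ICD-10-PCS shaped, stored without periods.",
  "egs_dx": {
    "appendicitis": ["K352", "K353", "K3580", "K36", "K37"],
    "biliary_disease": ["K800", "K801", "K8012", "K810", "K811", "K830"],
    "bowel_obstruction": ["K560", "K565", "K566", "K567"],
    "diverticulitis": ["K572", "K573", "K5792"],
    "peptic_ulcer": ["K251", "K254", "K255", "K265"],
    "hernia": ["K400", "K410", "K420", "K430", "K460"],
    "pancreatitis": ["K850", "K851", "K859"],
    "soft_tissue_infection": ["L0311", "M7266", "N492"]
  },
  "complication_dx": [
    "I214", "I2699", "I824", "J189", "J9600", "J9601",
    "K910", "N170", "R579", "T814XXA"
  ],
  "operation_proc": [
    "0DTJ4ZZ", "0FT44ZZ", "0DBB0ZZ", "0DN80ZZ", "0WJG4ZZ",
    "0W9G30Z", "0DJD8ZZ", "0FC98ZZ", "0DTN0ZZ", "0DQ90ZZ"
  ]
}
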