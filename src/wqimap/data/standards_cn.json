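{
  "description": "Default regulatory limits for the 16 routine drinking-water indicators, populated from China's national drinking-water quality standard (GB 5749-2006). User-editable configuration: limits are read from this file (or a user-supplied replacement), never hard-coded.",
  "entries": [
    {"code": "color", "category": "general", "limit": 15.0, "units": "PCU"},
    {"code": "turbidity", "category": "general", "limit": 1.0, "units": "NTU"},
    {"code": "odor", "category": "general", "limit": 3.0, "units": "TON"},
    {"code": "ph", "category": "ph", "limit": null, "units": "pH units"},
    {"code": "hardness", "category": "general", "limit": 450.0, "units": "mg/L as CaCO3"},
    {"code": "iron", "category": "general", "limit": 0.3, "units": "mg/L"},
    {"code": "manganese", "category": "general", "limit": 0.1, "units": "mg/L"},
    {"code": "sulfate", "category": "general", "limit": 250.0, "units": "mg/L"},
    {"code": "chloride", "category": "general", "limit": 250.0, "units": "mg/L"},
    {"code": "tds", "category": "general", "limit": 1000.0, "units": "mg/L"},
    {"code": "cod_mn", "category": "general", "limit": 3.0, "units": "mg/L O2"},
    {"code": "fluoride", "category": "general", "limit": 1.0, "units": "mg/L"},
    {"code": "arsenic", "category": "general", "limit": 0.01, "units": "mg/L"},
    {"code": "nitrate", "category": "general", "limit": 10.0, "units": "mg/L as N"},
    {"code": "tc", "category": "microbial", "limit": null, "units": "CFU/100 mL"},
    {"code": "tcb", "category": "microbial", "limit": null, "units": "CFU/100 mL"}
  ]
}
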