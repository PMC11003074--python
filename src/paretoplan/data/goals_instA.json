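[
 {"roi": "PTV60", "kind": "D_percent", "parameter": 99, "limit": 57.0, "limit_type": "ge", "description": "PTV60 D99% >= 95% presc"},
 {"roi": "PTV57.5", "kind": "D_percent", "parameter": 99, "limit": 54.625, "limit_type": "ge", "description": "PTV57.5 D99% >= 95% presc"},
 {"roi": "PTV48", "kind": "D_percent", "parameter": 99, "limit": 45.6, "limit_type": "ge", "description": "PTV48 D99% >= 95% presc"},
 {"roi": "PTV57.5-PTV60", "kind": "D_percent", "parameter": 50, "limit": 57.5, "limit_type": "ge", "description": "PTV57.5-PTV60 D50% >= 57.5 Gy"},
 {"roi": "PTV48-PTV57.5", "kind": "D_percent", "parameter": 50, "limit": 48.0, "limit_type": "ge", "description": "PTV48-PTV57.5 D50% >= 48 Gy"},
 {"roi": "PTV60", "kind": "D_percent", "parameter": 1, "limit": 63.0, "limit_type": "le", "description": "PTV60 D1% <= 63 Gy"},
 {"roi": "external", "kind": "D_abs_volume", "parameter": 1.8, "limit": 63.0, "limit_type": "le", "description": "Patient outline D1.8cm3 <= 63 Gy"},
 {"roi": "rectum", "kind": "V_dose_percent", "parameter": 24.3, "limit": 80.0, "limit_type": "le"},
 {"roi": "rectum", "kind": "V_dose_percent", "parameter": 32.4, "limit": 70.0, "limit_type": "le"},
 {"roi": "rectum", "kind": "V_dose_percent", "parameter": 40.5, "limit": 60.0, "limit_type": "le"},
 {"roi": "rectum", "kind": "V_dose_percent", "parameter": 48.6, "limit": 50.0, "limit_type": "le"},
 {"roi": "rectum", "kind": "V_dose_percent", "parameter": 52.7, "limit": 30.0, "limit_type": "le"},
 {"roi": "rectum", "kind": "V_dose_percent", "parameter": 56.8, "limit": 15.0, "limit_type": "le"},
 {"roi": "rectum", "kind": "V_dose_percent", "parameter": 60.0, "limit": 3.0, "limit_type": "le"},
 {"roi": "bladder", "kind": "V_dose_percent", "parameter": 40.5, "limit": 50.0, "limit_type": "le"},
 {"roi": "bladder", "kind": "V_dose_percent", "parameter": 48.6, "limit": 25.0, "limit_type": "le"},
 {"roi": "bladder", "kind": "V_dose_percent", "parameter": 60.0, "limit": 5.0, "limit_type": "le"}
]
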