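{
 "name": "CHHiP prostate 60Gy/20# (institution A)",
 "version": 1,
 "institution": "instA",
 "prescriptions": {"PTV60": 60.0, "PTV57.5": 57.5, "PTV48": 48.0},
 "prescription": 60.0,
 "goals": [
  {"roi": "PTV48", "priority": "P1", "goal_type": "conformality_max", "target": 46.8, "units": "Gy", "distance_cm": 1.5},
  {"roi": "PTV60", "priority": "P2", "goal_type": "min_dose", "target": 98.7, "units": "%Presc,PTV"},
  {"roi": "PTV60", "priority": "P2", "goal_type": "max_dose", "target": 101.7, "units": "%Presc,PTV"},
  {"roi": "PTV60", "priority": "P2", "goal_type": "median_max", "target": 99.5, "units": "%Presc,PTV"},
  {"roi": "PTV57.5", "priority": "P2", "goal_type": "min_dose", "target": 98.7, "units": "%Presc,PTV"},
  {"roi": "PTV57.5", "priority": "P2", "goal_type": "max_dose", "target": 102.5, "units": "%Presc,PTV"},
  {"roi": "PTV48", "priority": "P2", "goal_type": "min_dose", "target": 97.3, "units": "%Presc,PTV"},
  {"roi": "PTV48", "priority": "P2", "goal_type": "max_dose", "target": 104.9, "units": "%Presc,PTV"},
  {"roi": "rectum", "priority": "P3", "goal_type": "dv_max", "dose_level": 23.4, "target": 0.0, "units": "%Vol", "weighting_factor": 3.5},
  {"roi": "rectum", "priority": "P3", "goal_type": "dv_max", "dose_level": 31.5, "target": 0.0, "units": "%Vol", "weighting_factor": 3.5},
  {"roi": "rectum", "priority": "P3", "goal_type": "dv_max", "dose_level": 39.6, "target": 0.0, "units": "%Vol", "weighting_factor": 0.044},
  {"roi": "rectum", "priority": "P3", "goal_type": "dv_max", "dose_level": 47.7, "target": 0.0, "units": "%Vol", "weighting_factor": 0.088},
  {"roi": "rectum", "priority": "P3", "goal_type": "dv_max", "dose_level": 51.8, "target": 0.0, "units": "%Vol", "weighting_factor": 29.9},
  {"roi": "rectum", "priority": "P3", "goal_type": "dv_max", "dose_level": 55.9, "target": 0.0, "units": "%Vol", "weighting_factor": 3.5},
  {"roi": "rectum", "priority": "P3", "goal_type": "max_dose", "target": 60.0, "units": "Gy", "weighting_factor": 0.586},
  {"roi": "rectum", "priority": "P3", "goal_type": "mean_dose", "target": 5.0, "units": "Gy", "weighting_factor": 5.84},
  {"roi": "bladder", "priority": "P3", "goal_type": "dv_max", "dose_level": 30.0, "target": 0.0, "units": "%Vol", "weighting_factor": 0.316},
  {"roi": "bladder", "priority": "P3", "goal_type": "dv_max", "dose_level": 39.6, "target": 0.0, "units": "%Vol", "weighting_factor": 0.316},
  {"roi": "bladder", "priority": "P3", "goal_type": "dv_max", "dose_level": 47.7, "target": 0.0, "units": "%Vol", "weighting_factor": 0.316},
  {"roi": "bladder", "priority": "P3", "goal_type": "dv_max", "dose_level": 51.8, "target": 0.0, "units": "%Vol", "weighting_factor": 0.316},
  {"roi": "bladder", "priority": "P3", "goal_type": "dv_max", "dose_level": 55.9, "target": 0.0, "units": "%Vol", "weighting_factor": 0.316},
  {"roi": "bladder", "priority": "P3", "goal_type": "max_dose", "target": 54.0, "units": "Gy", "weighting_factor": 0.316},
  {"roi": "bladder", "priority": "P3", "goal_type": "mean_dose", "target": 5.0, "units": "Gy", "weighting_factor": 3.73},
  {"roi": "external", "priority": "P3", "goal_type": "dose_falloff_external", "falloff": {"high_dose": 60.0, "low_dose": 30.0, "gradient": 50.0}, "weighting_factor": 204.0},
  {"roi": "PTV57.5", "priority": "P3", "goal_type": "dose_falloff_intra", "falloff": {"high_dose": 54.0, "low_dose": 54.0, "gradient": 75.0}, "weighting_factor": 10.7},
  {"roi": "PTV48", "priority": "P3", "goal_type": "dose_falloff_intra", "falloff": {"high_dose": 54.6, "low_dose": 45.6, "gradient": 75.0}, "weighting_factor": 29.8}
 ]
}
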