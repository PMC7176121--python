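[
  {
    "name": "intussusception",
    "description": "Validation of diagnostic/procedural/billing-code case-finding algorithms for intussusception in children <18 years, Ottawa Census Metropolitan Area, 1995-2010 (Ducharme et al). Gold standard: manual chart review against the Brighton Collaboration criteria. Reported: PPV 72.4% (65.4-78.7), SE 89.3% (83.3-93.8), SP and NPV both >99.9%.",
    "n_subjects": 417997,
    "cfa_positives": 185,
    "gold_positives": 150,
    "specs": {
      "se": {"value": 0.893, "ci_lower": 0.833, "ci_upper": 0.938},
      "ppv": {"value": 0.724, "ci_lower": 0.654, "ci_upper": 0.787}
    },
    "expected": {
      "observed_prevalence_pct": "0.044",
      "true_prevalence_pct": "0.036",
      "derived_pi_pct_from_se_ppv": "0.036",
      "pi_ui_pct": ["0.034", "0.038"],
      "sp_npv_exceed": 0.999,
      "derived_se_pct_from_rounded_prevalences": "88.5",
      "rounded_inputs": {"p_pct": "0.044", "pi_pct": "0.036", "ppv_pct": "72.4"}
    }
  },
  {
    "name": "pneumonia",
    "description": "Validation of five claims-based pneumonia case-finding algorithms against manual review of emergency-department encounters, Salt Lake City (Aronsky et al). Selected algorithm: SE 65.1% (59.2-70.5), SP 99.6% (99.5-99.7), PPV 80.8% (75.1-85.5), NPV 99.1% (98.9-99.3).",
    "n_subjects": 10828,
    "cfa_positives": 219,
    "gold_positives": 272,
    "specs": {
      "se": {"value": 0.651, "ci_lower": 0.592, "ci_upper": 0.705},
      "sp": {"value": 0.996, "ci_lower": 0.995, "ci_upper": 0.997},
      "ppv": {"value": 0.808, "ci_lower": 0.751, "ci_upper": 0.855},
      "npv": {"value": 0.991, "ci_lower": 0.989, "ci_upper": 0.993}
    },
    "expected": {
      "observed_prevalence_pct": "2.02",
      "true_prevalence_pct": "2.51",
      "derived_pi_pct_from_ppv_npv": "2.51",
      "derived_sp_pct_from_ppv_npv": "99.6",
      "pi_ui_pct": ["2.4", "2.6"],
      "interval_run": {
        "pi_interval": [0.02, 0.03],
        "se_range_pct": ["54.4", "81.6"],
        "sp_range_pct": ["99.6", "99.6"],
        "npv_range_pct": ["98.6", "99.6"]
      },
      "rounded_inputs": {"p_pct": "2.02", "ppv_pct": "80.8", "npv_pct": "99.1"}
    }
  }
]
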