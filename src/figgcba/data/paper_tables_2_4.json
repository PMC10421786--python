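{
  "sexual_assault": {
    "name": "sexual_assault",
    "tangible_cost": {"kind": "triangular", "low": 5000, "mode": 7419, "high": 10000},
    "intangible_cost": {"kind": "triangular", "low": 100000, "mode": 133021, "high": 165000},
    "upload_increase": {"kind": "triangular", "low": 0.05, "mode": 0.10, "high": 0.20, "proportion": true},
    "upload_ratio": {"kind": "triangular", "low": 0.416, "mode": 0.45, "high": 0.50, "proportion": true},
    "category_share": {"kind": "uniform", "low": 0.135, "high": 0.20, "proportion": true},
    "total_cases": {"kind": "triangular", "low": 330000, "mode": 330000, "high": 400000},
    "lead_rate": {"kind": "triangular", "low": 0.59, "mode": 0.76, "high": 0.88, "proportion": true},
    "reduction_rate": {"kind": "triangular", "low": 0.30, "mode": 0.67, "high": 0.67, "proportion": true},
    "extra_hours": {"kind": "triangular", "low": 10, "mode": 30, "high": 50},
    "police_hourly_rate": {"kind": "triangular", "low": 24, "mode": 46, "high": 71}
  },
  "other_crimes": {
    "name": "other_crimes",
    "tangible_cost": {"kind": "triangular", "low": 6000, "mode": 8261, "high": 15000},
    "intangible_cost": {"kind": "triangular", "low": 20000, "mode": 30942, "high": 40000},
    "upload_increase": {"kind": "triangular", "low": 0.05, "mode": 0.10, "high": 0.20, "proportion": true},
    "upload_ratio": {"kind": "triangular", "low": 0.50, "mode": 0.55, "high": 0.60, "proportion": true},
    "category_share": {"kind": "uniform", "low": 0.80, "high": 0.865, "proportion": true},
    "total_cases": {"kind": "triangular", "low": 330000, "mode": 330000, "high": 400000},
    "lead_rate": {"kind": "triangular", "low": 0.59, "mode": 0.76, "high": 0.88, "proportion": true},
    "reduction_rate": {"kind": "triangular", "low": 0.30, "mode": 0.65, "high": 0.65, "proportion": true},
    "extra_hours": {"kind": "triangular", "low": 10, "mode": 30, "high": 50},
    "police_hourly_rate": {"kind": "triangular", "low": 24, "mode": 46, "high": 71},
    "hit_increase_share": {"kind": "uniform", "low": 0.135, "high": 0.20, "proportion": true}
  },
  "murder_category": {
    "name": "murder",
    "tangible_cost": {"kind": "triangular", "low": 2000000, "mode": 2658319, "high": 3000000},
    "intangible_cost": {"kind": "triangular", "low": 4000000, "mode": 5150836, "high": 6000000},
    "upload_increase": {"kind": "triangular", "low": 0.05, "mode": 0.10, "high": 0.20, "proportion": true},
    "upload_ratio": {"kind": "triangular", "low": 0.30, "mode": 0.40, "high": 0.50, "proportion": true},
    "category_share": {"kind": "point", "low": 1.0, "high": 1.0, "mode": 1.0, "proportion": true},
    "total_cases": {"kind": "triangular", "low": 6000, "mode": 6672, "high": 7100},
    "lead_rate": {"kind": "triangular", "low": 0.59, "mode": 0.76, "high": 0.88, "proportion": true},
    "reduction_rate": {"kind": "triangular", "low": 0.05, "mode": 0.15, "high": 0.15, "proportion": true},
    "extra_hours": {"kind": "triangular", "low": 10, "mode": 30, "high": 50},
    "police_hourly_rate": {"kind": "triangular", "low": 24, "mode": 46, "high": 71}
  },
  "murder": {
    "reported_murders": 17284,
    "clearance_rate": 0.614,
    "profile_yield": {"kind": "triangular", "low": 0.30, "mode": 0.40, "high": 0.50, "proportion": true},
    "horizon_years": 10,
    "serial_reduction": {"kind": "triangular", "low": 0.05, "mode": 0.15, "high": 0.15, "proportion": true}
  }
}
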