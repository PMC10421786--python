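{
  "reagents": {
    "kintelligence12_miseq_3plex": {"name": "kintelligence12_miseq_3plex", "library_kit_cost": 11499, "library_kit_size": 12, "run_kit_cost": 1500, "plexity": 3},
    "kintelligence12_miseq_6plex": {"name": "kintelligence12_miseq_6plex", "library_kit_cost": 11499, "library_kit_size": 12, "run_kit_cost": 1500, "plexity": 6},
    "kintelligence12_miseq_12plex": {"name": "kintelligence12_miseq_12plex", "library_kit_cost": 11499, "library_kit_size": 12, "run_kit_cost": 1500, "plexity": 12},
    "kintelligence12_miseq_30plex": {"name": "kintelligence12_miseq_30plex", "library_kit_cost": 11499, "library_kit_size": 12, "run_kit_cost": 1500, "plexity": 30},
    "kintelligence96_miseq_3plex": {"name": "kintelligence96_miseq_3plex", "library_kit_cost": 23000, "library_kit_size": 96, "run_kit_cost": 1500, "plexity": 3},
    "kintelligence96_miseq_12plex": {"name": "kintelligence96_miseq_12plex", "library_kit_cost": 23000, "library_kit_size": 96, "run_kit_cost": 1500, "plexity": 12},
    "kintelligence96_miseq_30plex": {"name": "kintelligence96_miseq_30plex", "library_kit_cost": 23000, "library_kit_size": 96, "run_kit_cost": 1500, "plexity": 30},
    "lib120_miseq_3plex": {"name": "lib120_miseq_3plex", "per_library_override": 120.0, "run_kit_cost": 1500, "plexity": 3},
    "lib120_miseq_12plex": {"name": "lib120_miseq_12plex", "per_library_override": 120.0, "run_kit_cost": 1500, "plexity": 12},
    "lib120_miseq_30plex": {"name": "lib120_miseq_30plex", "per_library_override": 120.0, "run_kit_cost": 1500, "plexity": 30},
    "kintelligence96_nextseq_96plex": {"name": "kintelligence96_nextseq_96plex", "library_kit_cost": 23000, "library_kit_size": 96, "run_kit_cost": 2737, "plexity": 96},
    "kintelligence96_nextseq_300plex": {"name": "kintelligence96_nextseq_300plex", "library_kit_cost": 23000, "library_kit_size": 96, "run_kit_cost": 2737, "plexity": 300},
    "lib120_nextseq_96plex": {"name": "lib120_nextseq_96plex", "per_library_override": 120.0, "run_kit_cost": 2737, "plexity": 96},
    "lib120_nextseq_300plex": {"name": "lib120_nextseq_300plex", "per_library_override": 120.0, "run_kit_cost": 2737, "plexity": 300},
    "figg_missing_person_reference": {"name": "figg_missing_person_reference", "library_kit_cost": 23000, "library_kit_size": 96, "run_kit_cost": 1500, "plexity": 30},
    "figg_missing_person_remains": {"name": "figg_missing_person_remains", "library_kit_cost": 23000, "library_kit_size": 96, "run_kit_cost": 1500, "plexity": 12},
    "current_missing_person_reference": {"name": "current_missing_person_reference", "per_library_override": 100.0, "run_kit_cost": 0, "plexity": 1},
    "current_missing_person_remains_low": {"name": "current_missing_person_remains_low", "per_library_override": 100.0, "run_kit_cost": 0, "plexity": 1},
    "current_missing_person_remains_high": {"name": "current_missing_person_remains_high", "per_library_override": 370.0, "run_kit_cost": 0, "plexity": 1},
    "cytosnp850_microarray_96": {"name": "cytosnp850_microarray_96", "library_kit_cost": 24480, "library_kit_size": 96, "run_kit_cost": 0, "plexity": 1},
    "gsa_microarray_1152": {"name": "gsa_microarray_1152", "library_kit_cost": 56448, "library_kit_size": 1152, "run_kit_cost": 0, "plexity": 1}
  },
  "caseload": {
    "requests_low": 330000,
    "requests_high": 400000,
    "samples_per_request": 5,
    "per_sample_high": 289.58,
    "per_sample_low": 170.0
  },
  "database_population": {
    "samples_per_year": 1000000,
    "per_sample_high": 298.58,
    "per_sample_high_text": 289.58,
    "per_sample_low": 120.0,
    "microarray_per_sample": 49.0,
    "note": "The published budget table prints $298,580,000 for database work while the narrative says $289,580,000 (= 1,000,000 x $289.58); the table value is internally consistent with the printed $943,090,000 total and is the default here."
  },
  "instruments": [
    {"name": "MiSeq FGx systems", "count": 200, "unit_cost": 180000, "printed_total": 36200000},
    {"name": "NextSeq 2000 systems", "count": 100, "unit_cost": 373000, "printed_total": 37300000},
    {"name": "Library prep robots", "count": 400, "unit_cost": 150000, "printed_total": 60000000},
    {"name": "Validation studies", "count": 200, "unit_cost": 100000, "printed_total": 20000000}
  ],
  "infrastructure": [
    {"name": "Sequencers", "total_cost": 73500000, "amortization_years": 10},
    {"name": "Robots", "total_cost": 60000000, "amortization_years": 10},
    {"name": "Validation studies", "total_cost": 20000000, "amortization_years": 10},
    {"name": "Miscellaneous", "total_cost": 50000000, "amortization_years": 1}
  ]
}
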