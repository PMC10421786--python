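{
  "total_forensic_profiles": 1144255,
  "lifetime_hits": 587773,
  "annual_uploads": 114426,
  "saki_completed_kits": 80325,
  "saki_uploaded": 33398,
  "saki_hits": 15784,
  "saki_serial_hits": 10550,
  "funding_low": 2000000000,
  "funding_high": 3000000000
}
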