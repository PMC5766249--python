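{
  "comment": "Clinically observed maximum-tolerated daily oral lapatinib doses (mg) by number of treatment days in a 5-day cycle: continuous dosing (5 days), a 2-day pulse, and a single-day clinical-expertise limit.",
  "points": [
    {"days": 1, "max_daily_oral_mg": 7000},
    {"days": 2, "max_daily_oral_mg": 5250},
    {"days": 5, "max_daily_oral_mg": 3000}
  ]
}
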