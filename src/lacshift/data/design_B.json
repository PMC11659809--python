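{
  "name": "B",
  "reactor_type": "shaken",
  "V0_L": 30.0,
  "Xv0_cells_per_mL": 2320000.0,
  "GLC0_g_per_L": 9.6,
  "GLN0_mmol_per_L": 4.0,
  "duration_h": 164.0,
  "feed_start_h": 48.0,
  "feed_schedule_pct_per_day": [
    [
      2,
      5.0
    ],
    [
      3,
      10.0
    ],
    [
      5,
      12.0
    ]
  ],
  "feed_GLC_g_per_L": 120.0,
  "feed_GLN_mmol_per_L": 0.0,
  "do_mode": "schedule",
  "do_setpoints_pct": [
    [
      0.0,
      50.0
    ],
    [
      92.0,
      10.0
    ]
  ],
  "do_shift_check_h": 92.0,
  "do_shift_trigger_cells_per_mL": 50000000.0
}
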