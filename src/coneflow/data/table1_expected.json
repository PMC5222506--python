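{
  "comment": "Published per-group summaries for the packaged study table, stored as printed strings; reproduce_table1 compares recomputed values at the printed precision. The non-flow HPi dispersion is omitted: the printed value (0.013) matches the standard error of the eight per-case values, not their SD (0.039). The age summary stores the printed median (43); the printed 'average age, 43.3' does not equal the mean of the per-case ages (43.0).",
  "n_rows": 11,
  "n_normal": 3,
  "n_nonflow": 8,
  "groups": {
    "age_y": {"normal_mean": "39.3", "normal_sd": "7.8", "nonflow_mean": "44.4", "nonflow_sd": "12.5", "p": "0.54"},
    "duration_y": {"normal_mean": "13.0", "normal_sd": "11.3", "nonflow_mean": "12.9", "nonflow_sd": "9.6", "p": "0.99"},
    "hba1c_pct": {"normal_mean": "9.7", "normal_sd": "2.0", "nonflow_mean": "7.7", "nonflow_sd": "1.3", "p": "0.084"},
    "dcp_density_pct": {"normal_mean": "60.14", "normal_sd": "2.91", "nonflow_mean": "50.21", "nonflow_sd": "5.21", "p": "0.016"},
    "hpi": {"normal_mean": "0.431", "normal_sd": "0.002", "nonflow_mean": "0.358", "p": "0.013"}
  },
  "spearman": {"r": "0.681", "p": "0.030", "n": 10},
  "median_age_y": "43",
  "median_duration_y": "8"
}
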