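{
 "version": 1,
 "component_label": "public",
 "pgen_log10_edges": [-12.0, -9.0, -6.0],
 "incidence_edges": [0.0, 0.02, 0.05, 0.1, 0.2, 0.3, 1.0],
 "rows": [
  [0.80, 0.10, 0.05, 0.03, 0.015, 0.005],
  [0.82, 0.09, 0.05, 0.025, 0.010, 0.005],
  [0.85, 0.08, 0.04, 0.02, 0.008, 0.002],
  [0.70, 0.12, 0.08, 0.06, 0.03, 0.01]
 ]
}
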