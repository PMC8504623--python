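{
  "lambda": 0.27595902156111984,
  "K": 0.06604326990328216,
  "n_pairs": 100000,
  "seed": 20240801,
  "query_len_range": [
    9,
    14
  ],
  "target_len_range": [
    50,
    300
  ],
  "matrix": "PAM40",
  "gap_open": 16,
  "gap_extend": 2
}
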