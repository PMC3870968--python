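{
 "asp_col": 257,
 "lys_col": 315,
 "n_columns": 428,
 "generator_seed": 20130101,
 "column_kinds": "vvvvvvvvvvvvvvvvvvvvsssssssssscccvvvvvvvvvvvvvvvsssssssssccccvvvvvvvvvvvvvvvvvvvvsssssssscccvvvvvvvvvvvvvvvsssssssccvvvvvvvvvvvvsssssssssccccvvvvvvvvvvvvvvvvvvvvvvvvvsssssssscccvvvvvvvvvvvvvvvvvvsssssscccvvvvvvvvvvvvssssssssssccccvvvvvvvvvvvvvvvvvvvvvvvvvssssssssscccvvvvvvvvvvvvvvvvvvvvsssssssccccvvvvvvvvvvvvvvvssssssssccccvvvvvvvvvvvvvvvvvvvvvvvvvssssssssscccvvvvvvvvvvvvvvvvvvssssssssvvvvvvvvvvvvvvvvvvvvvvvvvvvvvvvvvvvvvvvv",
 "rate_by_kind": {
  "s": 0.3,
  "c": 0.6,
  "v": 1.0
 }
}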