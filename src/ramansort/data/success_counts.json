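{
  "mock_morphology": {"n_positive": 26, "n_sorted": 60},
  "mock_cd_sort": {"n_positive": 9, "n_sorted": 33},
  "mock_carotenoid_sort": {"n_positive": 10, "n_sorted": 33},
  "mock_overall": {"n_positive": 45, "n_sorted": 126},
  "soil_overall": {"n_positive": 14, "n_sorted": 34},
  "soil_carotenoid_16s": {"n_positive": 7, "n_sorted": 11}
}
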