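{
  "MEP": ["dxs", "dxr", "ispD", "ispE", "ispF", "ispG", "ispH", "idi", "ispA"],
  "beta_carotene": ["crtE", "crtB", "crtI", "lcyB"],
  "astaxanthin": ["crtW", "crtZ"]
}
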