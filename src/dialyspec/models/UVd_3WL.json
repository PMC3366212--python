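{
 "name": "UVd_3WL",
 "signal_kind": "derivative",
 "intercept": -3.56,
 "terms": [
  {
   "wavelength_nm": 300,
   "coefficient": -1128.73
  },
  {
   "wavelength_nm": 270,
   "coefficient": 120.74
  },
  {
   "wavelength_nm": 222,
   "coefficient": -32.54
  }
 ],
 "provenance": {
  "source": "published",
  "fitted": false
 }
}
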