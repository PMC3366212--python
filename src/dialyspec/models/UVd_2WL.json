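{
 "name": "UVd_2WL",
 "signal_kind": "derivative",
 "intercept": -2.12,
 "terms": [
  {
   "wavelength_nm": 300,
   "coefficient": -1111.09
  },
  {
   "wavelength_nm": 270,
   "coefficient": 128.67
  }
 ],
 "provenance": {
  "source": "published",
  "fitted": false
 }
}
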