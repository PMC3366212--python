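{
 "name": "UVa_3WL",
 "signal_kind": "absorbance",
 "intercept": -1.55,
 "terms": [
  {
   "wavelength_nm": 294,
   "coefficient": 75.38
  },
  {
   "wavelength_nm": 312,
   "coefficient": -62.27
  },
  {
   "wavelength_nm": 266,
   "coefficient": -7.36
  }
 ],
 "provenance": {
  "source": "published",
  "fitted": false
 }
}
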