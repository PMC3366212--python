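{
 "name": "UVa_2WL",
 "signal_kind": "absorbance",
 "intercept": -1.67,
 "terms": [
  {
   "wavelength_nm": 294,
   "coefficient": 60.56
  },
  {
   "wavelength_nm": 312,
   "coefficient": -60.75
  }
 ],
 "provenance": {
  "source": "published",
  "fitted": false
 }
}
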