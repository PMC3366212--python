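{
 "name": "UVa_1WL",
 "signal_kind": "absorbance",
 "intercept": -2.28,
 "terms": [
  {
   "wavelength_nm": 294,
   "coefficient": 51.69
  }
 ],
 "provenance": {
  "source": "published",
  "fitted": false
 }
}
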