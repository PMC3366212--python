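{
 "name": "UVd_1WL",
 "signal_kind": "derivative",
 "intercept": -1.44,
 "terms": [
  {
   "wavelength_nm": 300,
   "coefficient": -1038.84
  }
 ],
 "provenance": {
  "source": "published",
  "fitted": false
 }
}
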