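{
  "description": "Molar extinction coefficients for hemoglobin in 1/(cm*M), compiled tabulated values (Prahl/OMLC compilation) at the two acquisition wavelengths.",
  "units": "cm^-1 M^-1",
  "wavelengths_nm": [690, 830],
  "hbo": {"690": 276.0, "830": 974.0},
  "hbr": {"690": 2051.96, "830": 693.04}
}
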