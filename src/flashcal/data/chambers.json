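{
  "_comment": "Synthetic chamber registry. Geometry and reference conditions reflect the published chamber types; n_dw_gy_per_c and k_q are NON-PHYSICAL placeholders (no calibration certificates are shipped) so the dose chain is runnable end to end. Replace with certificate values for real work.",
  "chambers": [
    {
      "name": "PTW-34001 Roos",
      "geometry": "plane-parallel",
      "volume_cm3": 0.35,
      "electrode_spacing_mm": 2.0,
      "n_dw_gy_per_c": 1.0e9,
      "k_q": 1.0,
      "calibration_lab": "NPL",
      "operating_voltage_V": -400.0,
      "_n_dw_placeholder": true
    },
    {
      "name": "PTW-30013 Farmer",
      "geometry": "cylindrical",
      "volume_cm3": 0.6,
      "electrode_spacing_mm": 3.05,
      "n_dw_gy_per_c": 1.0e9,
      "k_q": 1.0,
      "calibration_lab": "NPL",
      "operating_voltage_V": -400.0,
      "_n_dw_placeholder": true
    },
    {
      "name": "PTW-34045 Advanced Markus",
      "geometry": "plane-parallel",
      "volume_cm3": 0.02,
      "electrode_spacing_mm": 1.0,
      "n_dw_gy_per_c": 1.0e9,
      "k_q": 1.0,
      "calibration_lab": "NIST",
      "operating_voltage_V": -400.0,
      "_n_dw_placeholder": true
    },
    {
      "name": "IBA PPC05 #948",
      "geometry": "plane-parallel",
      "volume_cm3": 0.05,
      "electrode_spacing_mm": 0.6,
      "n_dw_gy_per_c": 1.0e9,
      "k_q": 1.0,
      "calibration_lab": "NIST",
      "operating_voltage_V": -400.0,
      "_n_dw_placeholder": true
    },
    {
      "name": "IBA PPC05 #1109",
      "geometry": "plane-parallel",
      "volume_cm3": 0.05,
      "electrode_spacing_mm": 0.6,
      "n_dw_gy_per_c": 1.0e9,
      "k_q": 1.0,
      "calibration_lab": "NPL",
      "operating_voltage_V": -400.0,
      "_n_dw_placeholder": true
    }
  ]
}
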