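{
  "mtd": [
    {"name": "schedule1", "treatment_days": [1, 2, 3, 4, 5], "oral_mg": 3000, "serum_peak_ng_ml": 1972, "tumor_peak_nM": 1275},
    {"name": "schedule2", "treatment_days": [1, 2, 3, 4], "oral_mg": 3642, "serum_peak_ng_ml": 2083, "tumor_peak_nM": 1347},
    {"name": "schedule3", "treatment_days": [1, 2, 3], "oral_mg": 4475, "serum_peak_ng_ml": 2202, "tumor_peak_nM": 1424},
    {"name": "schedule4", "treatment_days": [1, 2], "oral_mg": 5250, "serum_peak_ng_ml": 2294, "tumor_peak_nM": 1483},
    {"name": "schedule5", "treatment_days": [1], "oral_mg": 7000, "serum_peak_ng_ml": 2460, "tumor_peak_nM": 1590}
  ],
  "fixed_total_dose": [
    {"name": "schedule1", "treatment_days": [1, 2, 3, 4, 5], "oral_mg": 1400, "serum_peak_ng_ml": 1534, "tumor_peak_nM": 1025},
    {"name": "schedule2", "treatment_days": [1, 2, 3, 4], "oral_mg": 1750, "serum_peak_ng_ml": 1661, "tumor_peak_nM": 1074},
    {"name": "schedule3", "treatment_days": [1, 2, 3], "oral_mg": 2330, "serum_peak_ng_ml": 1826, "tumor_peak_nM": 1181},
    {"name": "schedule4", "treatment_days": [1, 2], "oral_mg": 5250, "serum_peak_ng_ml": 2294, "tumor_peak_nM": 1483},
    {"name": "schedule5", "treatment_days": [1], "oral_mg": 7000, "serum_peak_ng_ml": 2460, "tumor_peak_nM": 1590}
  ],
  "comment": "Tumor peaks are the serum peaks converted with the 0.61 tumor/serum ratio and 943.5 g/mol molecular weight. The fixed-total-dose schedule3 tumor peak is recomputed from its serum value (the conversion is linear); a transcription inconsistency in one published row was resolved in favor of the conversion formula."
}
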