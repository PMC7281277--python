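{
  "version": "1.0",
  "description": "Final 22-coefficient multiple regression predictor of log10 total free urinary cortisol (ug) from 14 standardized log10 VOC abundances with sex and time-of-day interactions. Reference cell: female, evening (all dummies zero). Coefficients at printed 3-decimal precision.",
  "response": "log10(cortisol_ug)",
  "intercept": {"coef": 0.496, "ci95": [0.446, 0.548], "p_bh": 2e-16},
  "main_terms": [
    {"label": "x1", "compound": "6-Methyl-5-hepten-2-one", "hmdb": "HMDB0035915", "class": "Ketone", "coef": -0.116, "ci95": [-0.174, -0.058], "p_bh": 2.93e-06, "rt1_s": 1364, "rt2_s": 0.76, "ri": 1031, "id_level": 1},
    {"label": "x2", "compound": "Ketone 1", "hmdb": null, "class": "Ketone", "coef": 0.170, "ci95": [0.093, 0.247], "p_bh": 4.18e-08, "rt1_s": 2056, "rt2_s": 0.75, "ri": 1403, "id_level": 4},
    {"label": "x3", "compound": "Unknown 1", "hmdb": null, "class": null, "coef": 0.035, "ci95": [-0.048, 0.117], "p_bh": 2.16e-08, "rt1_s": 1102, "rt2_s": 0.94, "ri": 911, "id_level": 4},
    {"label": "x4", "compound": "Hydrocarbon 1", "hmdb": null, "class": "Hydrocarbon", "coef": -0.069, "ci95": [-0.127, 0.012], "p_bh": 2.70e-03, "rt1_s": 1926, "rt2_s": 0.57, "ri": 1326, "id_level": 4},
    {"label": "x5", "compound": "Unknown 2", "hmdb": null, "class": null, "coef": -0.112, "ci95": [-0.169, -0.055], "p_bh": 4.57e-03, "rt1_s": 1510, "rt2_s": 1.03, "ri": 1102, "id_level": 4},
    {"label": "x6", "compound": "Unknown 3", "hmdb": null, "class": null, "coef": 0.207, "ci95": [0.105, 0.308], "p_bh": 4.79e-03, "rt1_s": 2270, "rt2_s": 1.00, "ri": 1538, "id_level": 4},
    {"label": "x7", "compound": "Unknown 4", "hmdb": null, "class": null, "coef": -0.040, "ci95": [-0.095, 0.014], "p_bh": 4.08e-02, "rt1_s": 512, "rt2_s": 1.47, "ri": 644, "ri_extrapolated": true, "id_level": 4},
    {"label": "x8", "compound": "Unknown 5", "hmdb": null, "class": null, "coef": -0.115, "ci95": [-0.173, -0.057], "p_bh": 6.37e-02, "rt1_s": 918, "rt2_s": 0.64, "ri": 830, "id_level": 4},
    {"label": "x9", "compound": "Unknown 6", "hmdb": null, "class": null, "coef": -0.035, "ci95": [-0.112, 0.042], "p_bh": 6.80e-02, "rt1_s": 2038, "rt2_s": 0.52, "ri": 1392, "id_level": 4},
    {"label": "x10", "compound": "Unknown 7", "hmdb": null, "class": null, "coef": 0.004, "ci95": [-0.095, 0.104], "p_bh": 1.57e-02, "rt1_s": 2156, "rt2_s": 0.54, "ri": 1456, "id_level": 4},
    {"label": "x11", "compound": "Pyrrole", "hmdb": "HMDB0035924", "class": "Heteroaromatic", "coef": 0.070, "ci95": [0.001, 0.139], "p_bh": 1.39e-01, "rt1_s": 926, "rt2_s": 1.87, "ri": 833, "id_level": 1},
    {"label": "x12", "compound": "1-Iodo-2-methylundecane", "hmdb": "HMDB0062727", "class": "Halogenated Hydrocarbon", "coef": -0.063, "ci95": [-0.124, -0.003], "p_bh": 5.47e-02, "rt1_s": 2322, "rt2_s": 0.59, "ri": 1571, "id_level": 3},
    {"label": "x13", "compound": "Unknown 8", "hmdb": null, "class": null, "coef": 0.070, "ci95": [0.003, 0.137], "p_bh": 8.97e-02, "rt1_s": 2304, "rt2_s": 1.07, "ri": 1560, "id_level": 4},
    {"label": "x14", "compound": "4,6-Dimethyl-dodecane", "hmdb": "HMDB0062598", "class": "Hydrocarbon", "coef": 0.081, "ci95": [0.001, 0.161], "p_bh": 8.97e-02, "rt1_s": 1784, "rt2_s": 0.56, "ri": 1246, "id_level": 3}
  ],
  "interaction_terms": [
    {"label": "x2", "dummy": "Male", "compound": "Ketone 1", "coef": -0.121, "ci95": [-0.228, -0.013], "p_bh": 1.81e-02},
    {"label": "x9", "dummy": "Male", "compound": "Unknown 6", "coef": -0.100, "ci95": [-0.203, 0.005], "p_bh": 3.18e-02},
    {"label": "x10", "dummy": "Male", "compound": "Unknown 7", "coef": 0.121, "ci95": [0.004, 0.237], "p_bh": 7.41e-03},
    {"label": "x3", "dummy": "Morning", "compound": "Unknown 1", "coef": 0.210, "ci95": [0.076, 0.345], "p_bh": 6.82e-02},
    {"label": "x6", "dummy": "Morning", "compound": "Unknown 3", "coef": -0.295, "ci95": [-0.434, -0.155], "p_bh": 1.25e-01},
    {"label": "x14", "dummy": "Morning", "compound": "4,6-Dimethyl-dodecane", "coef": -0.075, "ci95": [-0.182, 0.031], "p_bh": 1.91e-01},
    {"label": "x6", "dummy": "Afternoon", "compound": "Unknown 3", "coef": -0.092, "ci95": [-0.218, 0.035], "p_bh": 1.80e-01}
  ]
}
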