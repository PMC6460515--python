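{
  "name": "Antepartum multinomial prediction model for operative delivery (Schuit et al. 2012, model 1)",
  "metadata": {
    "outcome": "mode of delivery in laboring women with high-risk singleton vertex pregnancies beyond 36 weeks",
    "coefficients_source": "published antepartum model coefficients (Schuit et al. 2012), transcribed digit for digit",
    "ranges_note": "Covariate ranges are plausible clinical ranges chosen for this package; the source publication does not report the development-data ranges. They are repo-chosen, not published values."
  },
  "categories": [
    {"label": "IVD-FD", "reference": false},
    {"label": "CS-FD", "reference": false},
    {"label": "IVD-FTP", "reference": false},
    {"label": "CS-FTP", "reference": false},
    {"label": "spontaneous", "reference": true}
  ],
  "covariates": [
    {"name": "age", "kind": "continuous", "unit": "years", "range": [16, 45]},
    {"name": "gestational_age", "kind": "continuous", "unit": "weeks", "range": [36, 43]},
    {"name": "nulliparous", "kind": "binary", "unit": "", "range": [0, 1]},
    {"name": "prev_cs", "kind": "binary", "unit": "", "range": [0, 1]},
    {"name": "female", "kind": "binary", "unit": "", "range": [0, 1]},
    {"name": "birthweight_100g", "kind": "continuous", "unit": "100 g", "range": [20, 50]},
    {"name": "diabetes", "kind": "binary", "unit": "", "range": [0, 1]}
  ],
  "intercepts": [-13.1, -15.6, -11.1, -15.4],
  "coefficients": [
    [0.029, 0.26, 2.05, 1.77, -0.19, -0.059, 0.32],
    [0.052, 0.32, 1.13, 1.06, -0.5, -0.079, 0.99],
    [0.054, 0.038, 3.39, 2.39, -0.25, 0.083, -0.24],
    [0.056, 0.13, 2.65, 2.23, -0.013, 0.12, 0.87]
  ]
}
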