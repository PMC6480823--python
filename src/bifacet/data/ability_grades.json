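{
  "n": 219,
  "scales": {
    "NS1": "continuous",
    "NS2": "continuous",
    "AN1": "continuous",
    "AN2": "continuous",
    "UN1": "continuous",
    "UN2": "continuous",
    "Math": "latent-response",
    "Eng": "latent-response"
  },
  "facets": {
    "NS": ["NS1", "NS2"],
    "AN": ["AN1", "AN2"],
    "UN": ["UN1", "UN2"]
  },
  "grade_proportions": {
    "Math": [0.123, 0.311, 0.297, 0.174, 0.096],
    "Eng": [0.059, 0.393, 0.338, 0.174, 0.037]
  },
  "description": "Mixed Pearson/polyserial/polychoric summary of six intelligence test halves (number series, verbal analogies, unfolding; odd-even split) and two school grades; variances of the continuous variables on the diagonal, grades on the unit-variance latent-response metric."
}
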