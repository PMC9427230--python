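# Demo synthetic comorbidity database: two planted disease patterns over
# a 20-code universe with light background noise.
n_transactions: 500
universe_size: 20
item_labels: [hypertension, diabetes, hyperlipidemia, cad, copd,
              d05, d06, d07, d08, d09, d10, d11, d12, d13, d14,
              d15, d16, d17, d18, d19]
patterns:
  - items: [hypertension, diabetes]
    prevalence: 0.35
  - items: [hyperlipidemia, cad]
    prevalence: 0.25
noise: 0.05
seed: 2022
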