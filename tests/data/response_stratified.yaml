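# See README for the schema; this is the two-stage design with
# response-by-initial-treatment feasibility strata (8 embedded regimes).
label: response-stratified
stages:
  - options: [0, 1]
    strata:
      - key: []
        feasible: [0, 1]
        probs: [0.5, 0.5]
  - options: [2, 3, 4, 5]
    key_features: [a1, response]
    strata:
      - key: [1, 1]
        feasible: [2, 5]
        probs: [0.5, 0.5]
      - key: [1, 0]
        feasible: [3, 5]
        probs: [0.5, 0.5]
      - key: [0, 1]
        feasible: [2, 4]
        probs: [0.5, 0.5]
      - key: [0, 0]
        feasible: [3, 4]
        probs: [0.5, 0.5]
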