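b4270660e44ad045957dcbbf0ebe8e9bc59ba2d3da34ced8c05a9a54eafc658a  lbp53_synthetic_incidence.csv
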