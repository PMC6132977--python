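# Two-group model with both heterogeneities, R0 held at 1.2
# (lambda_1, mu_1 range over (0, 2); lambda_2 = 2 - lambda_1, mu_2 = 2 - mu_1)
f: [0.5, 0.5]
lambda: [1.3, 0.7]
mu: [1.4, 0.6]
gamma: 1.0
R0: 1.2
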