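# Two-group model, heterogeneous infectivity: lambda = (5/3, 1/3)
f: [0.5, 0.5]
lambda: [1.6666666666666667, 0.3333333333333333]
mu: [1.0, 1.0]
gamma: 1.0
R0: 1.2
N: 100
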