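# Two-group model, heterogeneous infectivity: lambda = (2/51)*(50, 1)
f: [0.5, 0.5]
lambda: [1.9607843137254901, 0.0392156862745098]
mu: [1.0, 1.0]
gamma: 1.0
R0: 1.5
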