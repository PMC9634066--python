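# Alzheimer's-disease navigation: bifurcation parameter 15.2 slows every
# oscillator unit, no landmark is recognised, and path choice degenerates to
# competition-driven wandering until the step budget is exhausted.
preset: ad
start: 1
goal: 6
attention: 2.3
lam: 15.2
B: 1.5
As: 1.0
dt: 0.005
t_end: 80.0
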