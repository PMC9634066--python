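# Healthy navigation: start LM1, goal LM6, constant high attention.
# Initial perceived code carries a 0.2-code appearance jitter.
preset: fig12
start: 1
goal: 6
here_code: 4.2
goal_code: 9.0
attention: 2.3
lam: 0.2
B: 1.5
As: 1.0
dt: 0.005
t_end: 80.0
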