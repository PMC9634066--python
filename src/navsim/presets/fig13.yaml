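# Attention-deficit navigation: attention drops below the 1.5 threshold at
# the LM4 decision (step 3), the agent enters the LM10 branch and stays one
# step, then attention recovers and the route is corrected.
preset: fig13
start: 1
goal: 6
here_code: 4.2
goal_code: 9.0
attention: [2.3, 2.3, 2.3, 1.0, 1.0, 2.3]
lam: 0.2
B: 1.5
As: 1.0
dt: 0.005
t_end: 80.0
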