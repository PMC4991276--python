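# Openness-learning study: openness adapts to net payoffs.
experiment = "sim2"
rounds = 100000
replications = 1
k_values = [0.0, 0.25, 0.5, 0.75, 1.0]
recording_interval = 1000

[grid]
width = 20
height = 20
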