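# Group-formation study (scaled): shared openness, affinity dynamics,
# community detection on the final affinity network. Use --full for the
# full scale (2,000,000 cycles x 50 replications).
experiment = "sim3"
rounds = 200000
replications = 5
openness_values = [-1.0, -0.5, 0.0, 0.5, 1.0]
threshold = 0.5

[grid]
width = 8
height = 8
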