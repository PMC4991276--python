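# Payoff study: frozen uniform openness, payoff vs openness across prevalence.
experiment = "sim1"
rounds = 100000
replications = 1
k_values = [0.0, 0.25, 0.5, 0.75, 1.0]

[grid]
width = 20
height = 20
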