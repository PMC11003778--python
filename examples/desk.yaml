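# Desk-scale run: additive fitness with silencing cost (b = 0.2) at the
# intermediate rates; equilibrates near the analytic n_hat = 300.
N: 2000
u: 0.01
s: 0.001
r: 1.0e-6
fitness_mode: additive
a: 0.02
b: 0.2
k: 0.0
n0: 10
max_generations: 5000
replicates: 5
seed: 1
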