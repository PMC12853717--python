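# Desk-scale simulation grid (the full study grid is enabled via --full-grid:
# n in {30,45,60,100,200,300,400,500,1000}, censoring proportions
# {0.01,0.05,0.10,...,0.95}, both R-squared targets, 1000 replicates).
models: [1, 2]
settings: [S1, S2, S3, S4, S5]
n: [45, 300, 1000]
proportions: [0.1, 0.3, 0.5, 0.7, 0.9]
r2: [0.6]
reps: 200
seed: 1
methods: null  # null = every method applicable to the model's BLOQ role
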