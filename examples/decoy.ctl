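# Published study conditions; every key may be overridden.
# Simulation
N = 10000            # diploid individuals (half female)
generations = 15000
n_encounters = 20    # males met per female per generation
mu = 5.0e-5          # mutation rate per locus per transmitted gamete
jump_prob = 0.01     # fraction of mutations that are large steps (2-4)
window = 500         # generations per substitution-rate window
n_replicates = 20
seed = 1
init_male = 0
init_female = 5
init_decoy = 16
init_neutral = 30

# Model (see decoysim.conflict_model.ModelParams)
P_opt = 0.1
B_max = 10.0
s_w = 0.15
x_w = 1.5
s_p = 0.1
x_p = 2.0
si = 1.0
xi = 1.0
sd = 0.25
xd = 1.0
c0 = 0.2
D_opt = 0.1
allele_max = 50
normalize = true
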