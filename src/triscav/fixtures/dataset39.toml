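# Reference dimensionless parameter set for the prey-predator-scavenger
# model.  nu1 (predator harvesting) is the usual bifurcation dial; 0.07 is
# the reference value at which the coexistence equilibrium is stable.

[model]
kind = "nondim"
gamma = 0.9
A1 = 0.11
A2 = 0.13
A3 = 0.4
delta = 0.25
alpha = 0.3
beta = 13.0
mu = 10.5
nu1 = 0.07
nu2 = 0.3

[solver]
rtol = 1e-9
atol = 1e-11
t_end = 2000.0
transient = 3000.0

[orbit]
x0 = [0.4, 0.8, 0.02]

[analysis]
seed = 0
n_starts = 64
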