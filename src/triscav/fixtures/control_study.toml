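# Dimensional parameter set for the optimal quadratic-harvesting study.

[model]
kind = "dim"
r = 5.0
k = 0.9
a = 0.1
b = 0.25
c = 0.05
d = 0.25
n = 0.35
k1 = 0.1
k2 = 0.12
k3 = 0.48
l = 0.25
m = 0.2
q1 = 0.5
q2 = 0.5
E1 = 0.0
E2 = 0.0

[economics]
p1 = 1.0
p2 = 1.0
C1 = 1.0
C2 = 1.0
delta1 = 0.05
nu1_econ = 1.0
nu2_econ = 1.0
E1max = 1.0
E2max = 1.0
Tf = 5.0

[control]
X0 = [5.5, 2.5, 2.5]
n_grid = 2001
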