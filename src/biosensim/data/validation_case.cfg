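# Validation case: DNA-binding micro chamber, run for 1e5 s.
# Printed parameters (SI):
H = 1e-3
L = 1e-2
Ls = 1e-2
Q = 7e-11
c0 = 2.5e-6
bmax = 1.668e-8
kon = 75.0
koff = 1e-2
# Documented assumptions (not printed anywhere):
#  - D: diffusion coefficient typical of short DNA strands
#  - depth_W: 1 cm chamber depth for the Q -> u_mean conversion
#  - sensor: whole bottom wall (sensor_offset = 0, Ls = L)
D = 1e-10
depth_W = 0.01
sensor_offset = 0.0
rho = 1000.0
mu = 1e-3
# mesh and time controls
Nx = 101
Ny = 21
Ns = 101
dt = 10.0
t_end = 1e5
output_every = 10
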