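[material]
E_r_GPa = 15.9
E_z_GPa = 20.3
nu_r = 0.328
nu_z = 0.25
alpha = 0.132
alpha_prime = 0.092
N_GPa = 38.0
mu_Pa_s = 1e-3

[geometry]
a_um = 50.0
b_um = 150.0
n_layers = 6

[loading]
eps_z0 = 0.00092
omega_rad_s = 21.0

[layers]
k_m2 = [0.5e-18, 0.7e-18, 0.9e-18, 1.1e-18, 1.3e-18, 1.5e-18]
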