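# Human reference case (no feeding scenario exists for humans).
units: table
species: human
condition: control
L_S: 670.0
L_C: 268.0
alpha: 0.034
Gamma: 100.0
R_gas: 8.314
T_abs: 310.0
mu: 0.7e-3
u_RPE: 3.0e-8
p_orbit: 3.0
dP_blood: 5.0
dP_SCS: 1.0
EVP: 7.1
Q_prod: 2.53
C_fac: 0.26
Lp_star: 1.83e-7
K_S: 1.33e-18
K_C: 1.33e-16
D2_S: 9.6e-12
D3_S: 9.6e-12
D2_C: 8.75e-11
D3_C: 8.75e-11
beta: 3.4e-6
c_SA_blood_total: 0.68
c3_B: 2.5e-6         # mM (2.5 nM serum atRA:SA)
sigma: 1.0
k_prod: 1.01e-8
k_CYP_deg: 4.56e-5
Ind_max: 33.0
Ind_C50: 9.0e-5
f_u_inc: 0.4
A_S: 1.49e-3
Ka: 2.3e+6
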