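# Mouse after oral retinoic-acid feeding: identical to the control preset
# except for the blood atRA:SA concentration, set from the measured serum
# plateau 90 min after feeding (11.67 nmol/ml).
units: table
species: mouse
condition: feeding
L_S: 70.0
L_C: 30.0
alpha: 0.3
Gamma: 100.0
R_gas: 8.314
T_abs: 310.0
mu: 0.7e-3
u_RPE: 23.0e-8
p_orbit: 3.0
dP_blood: 5.0
dP_SCS: 1.0
EVP: 7.5
Q_prod: 48.0e-3
C_fac: 5.9e-3
Lp_star: 3.56e-5
K_S: 6.4e-18
K_C: 6.4e-16
D2_S: 9.6e-12
D3_S: 9.6e-12
D2_C: 8.75e-11
D3_C: 8.75e-11
beta: 1.37e-3
c_SA_blood_total: 0.41
c3_B: 1.167e-2       # mM (11.67 nmol/ml)
sigma: 1.0
k_prod: 7.8e-8
k_CYP_deg: 3.5e-4
Ind_max: 33.0
Ind_C50: 9.0e-5
f_u_inc: 0.4
A_S: 3.2e-5
Ka: 2.3e+6
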