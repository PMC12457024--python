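# Mouse reference case, no retinoic-acid feeding. Literature-style units
# ("table"): lengths um, pressures mmHg, flows ul/min, concentrations mM.
units: table
species: mouse
condition: control
L_S: 70.0            # um
L_C: 30.0            # um
alpha: 0.3
Gamma: 100.0
R_gas: 8.314         # J/mol/K
T_abs: 310.0         # K
mu: 0.7e-3           # Pa s
u_RPE: 23.0e-8       # m/s
p_orbit: 3.0         # mmHg
dP_blood: 5.0        # mmHg
dP_SCS: 1.0          # mmHg
EVP: 7.5             # mmHg
Q_prod: 48.0e-3      # ul/min
C_fac: 5.9e-3        # ul/min/mmHg
Lp_star: 3.56e-5     # 1/(s Pa)
K_S: 6.4e-18         # m^2
K_C: 6.4e-16         # m^2 (100 x K_S)
D2_S: 9.6e-12        # m^2/s
D3_S: 9.6e-12
D2_C: 8.75e-11
D3_C: 8.75e-11
beta: 1.37e-3        # 1/s
c_SA_blood_total: 0.41   # mM
c3_B: 1.25e-6        # mM (serum atRA:SA, control: 1.25 pmol/ml)
sigma: 1.0
k_prod: 7.8e-8       # mM/s
k_CYP_deg: 3.5e-4    # 1/s
Ind_max: 33.0
Ind_C50: 9.0e-5      # mM (90 nM)
f_u_inc: 0.4
A_S: 3.2e-5          # m^2
Ka: 2.3e+6            # 1/M
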