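# Units manifest: the unit of each parameter in "table"-unit files and the
# SI unit used internally. Concentration note: 1 mM == 1 mol m^-3.
L_C:  {table: um,          SI: m}
L_S:  {table: um,          SI: m}
alpha: {table: "1",        SI: "1"}
Gamma: {table: "1",        SI: "1"}
R_gas: {table: J/mol/K,    SI: J/mol/K}
T_abs: {table: K,          SI: K}
mu:   {table: Pa.s,        SI: Pa.s}
u_RPE: {table: m/s,        SI: m/s}
p_orbit: {table: mmHg,     SI: Pa}
dP_blood: {table: mmHg,    SI: Pa}
dP_SCS: {table: mmHg,      SI: Pa}
EVP:  {table: mmHg,        SI: Pa}
Q_prod: {table: ul/min,    SI: m^3/s}
C_fac: {table: ul/min/mmHg, SI: m^3/s/Pa}
Lp_star: {table: 1/s/Pa,   SI: 1/s/Pa}
K_S:  {table: m^2,         SI: m^2}
K_C:  {table: m^2,         SI: m^2}
D2_S: {table: m^2/s,       SI: m^2/s}
D3_S: {table: m^2/s,       SI: m^2/s}
D2_C: {table: m^2/s,       SI: m^2/s}
D3_C: {table: m^2/s,       SI: m^2/s}
beta: {table: 1/s,         SI: 1/s}
c_SA_blood_total: {table: mM, SI: mol/m^3}
c3_B: {table: mM,          SI: mol/m^3}
sigma: {table: "1",        SI: "1"}
k_prod: {table: mM/s,      SI: mol/m^3/s}
k_CYP_deg: {table: 1/s,    SI: 1/s}
Ind_max: {table: "1",      SI: "1"}
Ind_C50: {table: mM,       SI: mol/m^3}
f_u_inc: {table: "1",      SI: "1"}
A_S:  {table: m^2,         SI: m^2}
Ka:   {table: 1/M,         SI: 1/M}
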