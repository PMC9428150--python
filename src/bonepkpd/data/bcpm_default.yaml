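# Default bone cell population model constants (version 1).
# Units: rates 1/day, concentrations pM, k_res/k_form in % f_bm per day
# per pM, stresses MPa. k_form: null means "balanced against resorption at
# the healthy steady state" (computed at site initialization).
version: 1

Obu_pool: 1.0e-3
Ocu_pool: 1.0e-3
D_Obu: 0.7
D_Obp: 0.35
P_Obp: 0.05
Delta_Oba: 0.30
D_Ocu: 0.5
D_Ocp: 0.2
A_Oca_nom: 0.35
eta: 1.0
k_res_nom: 7.3
k_form: null

tgf_basal: 0.1
tgf_per_resorption: 100.0
K_tgf_obu: 0.55
K_tgf_obp: 0.18
K_tgf_ocp: 0.08

prl_per_obp: 40.0
d_rankl: 10.0
opg_per_oba: 1000.0
K_opg: 0.75
rank_per_ocp: 100.0
K_rank: 0.25
K_rl_ocu: 6.0e-3
K_rl_ocp: 6.0e-3
pth0: 1.0
K_pth_opg: 1.0

scl0: 1.0
K_scl: 1.0
wnt0: 1.0
K_wnt: 1.0
scl_mech_exp: 1.0

E0_MPa: 84370.0
stiff_exp_fbm: 2.58
stiff_exp_ash: 2.74
mech_hill_n: 1.0

ash_primary: 0.45
ash_max: 0.70
kappa_mineral: 8.0e-4
rho_tissue_a: 1.41
rho_tissue_b: 1.29
max_bins: 200

P_RANKL_max: 0.18
t_onset: 0.0
half_time: 730.0
gamma: 3.0

damage_on: false
dam_accum: 0.0
dam_repair: 0.0
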