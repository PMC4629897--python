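{
  "description": "Reference constant set and initial state of the Maleckar human atrial myocyte model (Nygren-lineage compartmental architecture with refit I_t and I_Kur). Units: s, mV, pA, nS, pF, mM, nL.",
  "constants": {
    "R": 8314.0,
    "T": 306.15,
    "F": 96487.0,
    "Cm": 50.0,
    "Vol_i": 0.005884,
    "Vol_d": 0.00011768,
    "Vol_c": 0.000800224,
    "Vol_rel": 4.41e-05,
    "Vol_up": 0.0003969,
    "P_Na": 0.0018,
    "g_CaL": 6.75,
    "E_Ca_app": 60.0,
    "k_Ca": 0.025,
    "g_t": 8.25,
    "g_kur": 2.25,
    "g_Ks": 1.0,
    "g_Kr": 0.5,
    "g_K1": 3.1,
    "g_B_Na": 0.060599,
    "g_B_Ca": 0.078681,
    "i_NaK_max": 68.55,
    "k_NaK_K": 1.0,
    "k_NaK_Na": 11.0,
    "i_CaP_max": 4.0,
    "k_CaP": 0.0002,
    "k_NaCa": 0.0374842,
    "gamma_Na": 0.45,
    "d_NaCa": 0.0003,
    "phi_Na_en": 0.0,
    "ACh": 1e-24,
    "tau_Na": 14.3,
    "tau_K": 10.0,
    "tau_Ca": 24.7,
    "Na_b": 130.0,
    "K_b": 5.4,
    "Ca_b": 1.8,
    "tau_di": 0.01,
    "I_up_max": 2800.0,
    "k_cyca": 0.0003,
    "k_srca": 0.5,
    "k_xcs": 0.4,
    "tau_tr": 0.01,
    "alpha_rel": 200000.0,
    "k_rel_i": 0.0003,
    "k_rel_d": 0.003,
    "r_recov": 0.815,
    "Mg_i": 2.5
  },
  "initial_state": {
    "V": -74.031982,
    "m": 0.0032017,
    "h1": 0.8814,
    "h2": 0.8742,
    "d_L": 1.3005e-05,
    "f_L1": 0.99861,
    "f_L2": 0.99862,
    "r": 0.0010678,
    "s": 0.949,
    "a_ur": 0.00015949,
    "i_ur": 0.9912,
    "n": 0.0048357,
    "pa": 5.0e-05,
    "Na_c": 130.022096,
    "K_c": 5.560224,
    "Ca_c": 1.815768,
    "Na_i": 8.516766,
    "K_i": 129.485991,
    "Ca_i": 6.729e-05,
    "Ca_d": 7.249e-05,
    "Ca_up": 0.649195,
    "Ca_rel": 0.632613,
    "O_C": 0.0275,
    "O_TC": 0.0133,
    "O_TMgC": 0.1961,
    "O_TMgMg": 0.7094,
    "O_Calse": 0.43686,
    "F1": 0.470923,
    "F2": 0.0028005
  }
}
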