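K_A: 4.0
K_A1: 4.0
K_F: 4.0
K_IPP: 0.02
K_MAX: 0.34
K_NH4: 0.05
K_NH4_AUT: 1.0
K_NO3: 0.5
K_O2: 0.2
K_O2_AUT: 0.5
K_P: 0.01
K_PHA: 0.0871
K_PP: 0.0605
K_PS: 0.2
K_X: 0.14
K_fe: 4.0
K_h: 3.0
Y_A: 0.24
Y_H: 0.62
Y_PAO: 0.625
Y_PHA: 0.4648
Y_PO4: 0.3
acclimation_profile: non_acclimated
b_AUT: 0.15
b_H: 0.1874
b_PAO: 0.0497
b_PHA: 0.2
b_PP: 0.2
eta_NO3_H: 0.5
eta_NO3_PAO: 0.303
eta_NO3_hyd: 0.9
eta_fe_hyd: 0.0462
f_SI: 0.0
f_XI: 0.1
i_N_BM: 0.07
i_N_SF: 0.03
i_N_SI: 0.01
i_N_XI: 0.02
i_N_XS: 0.04
i_P_BM: 0.02
i_P_SF: 0.01
i_P_SI: 0.0
i_P_XI: 0.01
i_P_XS: 0.01
i_TSS_BM: 0.9
i_TSS_PHA: 0.6
i_TSS_PP: 3.23
i_TSS_XI: 0.75
i_TSS_XS: 0.75
mu_AUT: 1.0
mu_H: 6.0
mu_H_A1: 0.1656
mu_PAO: 0.2
q_PHA: 2.7
q_PHA_A1: 0.0
q_PP: 2.0
q_fe: 3.0
q_fe_A1: 0.005
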