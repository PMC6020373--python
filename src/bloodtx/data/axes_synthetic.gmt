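axis_T	bloodtx-synthetic-placeholder	BIT_T_01	BIT_T_02	BIT_T_03	BIT_T_04	BIT_T_05	BIT_T_06	BIT_T_07	BIT_T_08	BIT_T_09	BIT_T_10
axis_B	bloodtx-synthetic-placeholder	BIT_B_01	BIT_B_02	BIT_B_03	BIT_B_04	BIT_B_05	BIT_B_06	BIT_B_07	BIT_B_08	BIT_B_09	BIT_B_10
axis_N	bloodtx-synthetic-placeholder	BIT_N_01	BIT_N_02	BIT_N_03	BIT_N_04	BIT_N_05	BIT_N_06	BIT_N_07	BIT_N_08	BIT_N_09	BIT_N_10
axis_R	bloodtx-synthetic-placeholder	BIT_R_01	BIT_R_02	BIT_R_03	BIT_R_04	BIT_R_05	BIT_R_06	BIT_R_07	BIT_R_08	BIT_R_09	BIT_R_10
axis_I	bloodtx-synthetic-placeholder	BIT_I_01	BIT_I_02	BIT_I_03	BIT_I_04	BIT_I_05	BIT_I_06	BIT_I_07	BIT_I_08	BIT_I_09	BIT_I_10
axis_G	bloodtx-synthetic-placeholder	BIT_G_01	BIT_G_02	BIT_G_03	BIT_G_04	BIT_G_05	BIT_G_06	BIT_G_07	BIT_G_08	BIT_G_09	BIT_G_10
axis_C	bloodtx-synthetic-placeholder	BIT_C_01	BIT_C_02	BIT_C_03	BIT_C_04	BIT_C_05	BIT_C_06	BIT_C_07	BIT_C_08	BIT_C_09	BIT_C_10
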