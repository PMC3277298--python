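(C_sp_1,(C_plicata,(((C_elegans,((C_remanei,(C_sp_5,(C_briggsae,C_sp_9))),(C_brenneri,(C_sp_11,(C_sp_10,C_sp_16))))),(C_sp_15,((C_japonica,C_sp_14),(C_sp_7,(C_sp_17,(C_sp_18,C_sp_19)))))),(C_sp_20,((C_sp_6,C_sp_13),((C_drosophilae,C_sp_2),(C_sp_8,(C_angaria,C_sp_12))))))));
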