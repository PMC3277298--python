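taxon	display_name	group
C_sp_1	Caenorhabditis sp. 1	basal
C_plicata	Caenorhabditis plicata	basal
C_elegans	Caenorhabditis elegans	Elegans group
C_remanei	Caenorhabditis remanei	Elegans group
C_sp_5	Caenorhabditis sp. 5	Elegans group
C_briggsae	Caenorhabditis briggsae	Elegans group
C_sp_9	Caenorhabditis sp. 9	Elegans group
C_brenneri	Caenorhabditis brenneri	Elegans group
C_sp_11	Caenorhabditis sp. 11	Elegans group
C_sp_10	Caenorhabditis sp. 10	Elegans group
C_sp_16	Caenorhabditis sp. 16	Elegans group
C_sp_15	Caenorhabditis sp. 15	Elegans super-group
C_sp_7	Caenorhabditis sp. 7	Japonica group
C_japonica	Caenorhabditis japonica	Japonica group
C_sp_14	Caenorhabditis sp. 14	Japonica group
C_sp_17	Caenorhabditis sp. 17	Japonica group
C_sp_18	Caenorhabditis sp. 18	Japonica group
C_sp_19	Caenorhabditis sp. 19	Japonica group
C_sp_20	Caenorhabditis sp. 20	Drosophilae super-group
C_sp_6	Caenorhabditis sp. 6	Drosophilae super-group
C_sp_13	Caenorhabditis sp. 13	Drosophilae super-group
C_drosophilae	Caenorhabditis drosophilae	Drosophilae group
C_sp_2	Caenorhabditis sp. 2	Drosophilae group
C_sp_8	Caenorhabditis sp. 8	Angaria group
C_angaria	Caenorhabditis angaria	Angaria group
C_sp_12	Caenorhabditis sp. 12	Angaria group
Protorhabditis_sp	Protorhabditis sp. (outgroup)	outgroup
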