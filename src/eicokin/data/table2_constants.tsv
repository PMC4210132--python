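reaction	form	parameter	value	unit
R1	activated_inhibited_mm	v_max	20.56	nM^2.s^-1
R1	activated_inhibited_mm	k_m	2500	uM
R1	activated_inhibited_mm	k_i	100	nM
R2	activated_inhibited_mm	v_max	0.01	nM^2.s^-1
R2	activated_inhibited_mm	k_m	0.0107	nM
R2	activated_inhibited_mm	k_i	8.603	nM
R3	first_order_decay	k_cat	0.0012	s^-1
R4	activated_inhibited_mm	v_max	9.7953	nM^2.s^-1
R4	activated_inhibited_mm	k_m	99.913	nM
R4	activated_inhibited_mm	k_i	0.709	nM
R5	first_order_decay	k_cat	0.0012	s^-1
R6	activated_inhibited_mm	v_max	0.003	nM^3.s^-1
R6	activated_inhibited_mm	k_m	0.067	nM
R6	activated_inhibited_mm	k_i	1.004	nM
R7	activated_inhibited_mm	v_max	1.098	nM.s^-1
R7	activated_inhibited_mm	k_m	1.58	nM
R7	activated_inhibited_mm	k_i	0.0106	nM
R8	first_order_decay	k_cat	0.00127	s^-1
R9	activated_inhibited_mm	v_max	0.168	nM.s^-1
R9	activated_inhibited_mm	k_m	3.876	nM
R9	activated_inhibited_mm	k_i	0.013	nM
R10	activated_linear	v_max	0.067	s^-1
R11	first_order_decay	k_cat	0.052	s^-1
R12	first_order_decay	k_cat	0.00096	s^-1
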