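variable	timepoint	high_wl_mean	high_wl_sd	low_wl_mean	low_wl_sd
female_pct	baseline	64.5		65.7
age_years	baseline	42.2	6.7	42.5	5.7
weight_loss_pct	2m	12.3	2.9	10.0	1.9
weight_loss_pct	8m	15.4	4.6	5.8	3.4
weight_kg	baseline	100.4	18.3	97.7	16.7
weight_kg	2m	87.9	15.9	88.0	15.1
weight_kg	8m	84.8	15.8	92.0	15.7
bmi_kg_m2	baseline	34.6	4.8	34.0	4.4
cholesterol_mmol_l	baseline	4.8	0.9	4.9	1.1
ldl_mmol_l	baseline	3.0	0.8	3.1	0.9
hdl_mmol_l	baseline	1.2	0.3	1.3	0.3
tag_mmol_l	baseline	1.4	0.6	1.4	0.7
nefa_umol_l	baseline	680	294	640	281
glucose_mmol_l	baseline	5.1	0.6	5.1	0.6
insulin_mu_l	baseline	12.6	18.1	10.9	6.5
homa_ir	baseline	3.4	5.0	2.9	1.9
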