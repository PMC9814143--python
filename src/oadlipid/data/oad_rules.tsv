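rule_id	bond_site	hydrogen_delta	oxygen_delta	water_loss	rel_intensity	diagnostic	applicability
OAD01	-1	-1	1	0	0.03	0	acyl
OAD02	-1	-1	1	1	0.02	0	acyl
OAD03	-1	0	1	0	0.10	1	acyl
OAD04	-1	0	1	1	0.03	0	acyl
OAD05	-1	1	1	0	0.03	0	acyl
OAD06	-1	1	1	1	0.02	0	acyl
OAD07	0	-1	1	0	0.03	0	acyl
OAD08	0	0	1	0	0.05	0	acyl
OAD09	0	0	1	1	0.02	0	acyl
OAD10	0	1	1	0	0.03	0	acyl
OAD11	0	-1	0	0	0.02	0	acyl
OAD12	0	0	0	0	0.03	0	acyl
OAD13	0	1	0	0	0.02	0	acyl
OAD14	1	-1	0	0	0.03	0	acyl
OAD15	1	-1	0	1	0.02	0	acyl
OAD16	1	0	0	0	0.10	1	acyl
OAD17	1	0	0	1	0.02	0	acyl
OAD18	1	1	0	0	0.03	0	acyl
OAD19	1	0	1	0	0.02	0	acyl
OAD20	1	1	1	0	0.02	0	acyl
D4-03	-1	0	1	0	0.01	1	sphingoid_delta4
D4-16	1	0	0	0	0.01	1	sphingoid_delta4
VE-01	-1	0	1	0	0.05	0	vinyl_ether
VE-02	-1	-1	1	0	0.05	0	vinyl_ether
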