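trait	cut1	cut2	cut3	cut4	unit
growth_rate	5	20	40	80	mm/yr
skeletal_density	0.8	1.2	1.6	2.0	g/cm3
colony_size	10	30	60	120	cm
colony_height	5	15	30	60	cm
corallite_width	1	2	5	10	mm
space_size	2	5	10	20	mm
sav_ratio	0.5	1	2	4	1/cm
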