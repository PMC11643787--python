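symbol	IP_eV	EA_eV	r_cov_A	logp_contrib
H	13.598	0.754	0.31	0.123
C	11.260	1.262	0.76	0.110
N	14.534	-0.070	0.71	-0.600
O	13.618	1.461	0.66	-0.397
F	17.423	3.401	0.57	0.224
P	10.487	0.746	1.07	-0.447
S	10.360	2.077	1.05	0.255
Cl	12.968	3.613	1.02	0.530
Br	11.814	3.364	1.20	0.762
I	10.451	3.059	1.39	1.050
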