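# element	isotope_mass_da	abundance_fraction
H	1.007825032	0.999885000
H	2.014101778	0.000115000
C	12.000000000	0.989300000
C	13.003354838	0.010700000
N	14.003074005	0.996360000
N	15.000108898	0.003640000
O	15.994914620	0.997570000
O	16.999131700	0.000380000
O	17.999161000	0.002050000
F	18.998403220	1.000000000
Na	22.989769281	1.000000000
Mg	23.985041700	0.789900000
Mg	24.985836920	0.100000000
Mg	25.982592929	0.110100000
Al	26.981538630	1.000000000
Si	27.976926532	0.922230000
Si	28.976494700	0.046850000
Si	29.973770170	0.030920000
P	30.973761630	1.000000000
S	31.972071000	0.949900000
S	32.971458760	0.007500000
S	33.967866900	0.042500000
S	35.967080760	0.000100000
Cl	34.968852680	0.757600000
Cl	36.965902590	0.242400000
K	38.963706680	0.932581000
K	39.963998480	0.000117000
K	40.961825760	0.067302000
Ca	39.962590980	0.969410000
Ca	41.958618010	0.006470000
Ca	42.958766600	0.001350000
Ca	43.955481800	0.020860000
Ca	45.953692600	0.000040000
Ca	47.952534000	0.001870000
Cr	49.946044200	0.043450000
Cr	51.940507500	0.837890000
Cr	52.940649400	0.095010000
Cr	53.938880400	0.023650000
Mn	54.938045100	1.000000000
Fe	53.939610500	0.058450000
Fe	55.934937500	0.917540000
Fe	56.935394000	0.021190000
Fe	57.933275600	0.002820000
Co	58.933195000	1.000000000
Ni	57.935342900	0.680769000
Ni	59.930786400	0.262231000
Ni	60.931056000	0.011399000
Ni	61.928345100	0.036345000
Ni	63.927966000	0.009256000
Cu	62.929597500	0.691500000
Cu	64.927789500	0.308500000
Zn	63.929142200	0.482680000
Zn	65.926033400	0.279750000
Zn	66.927127300	0.041020000
Zn	67.924844200	0.190240000
Zn	69.925319300	0.006310000
As	74.921596500	1.000000000
Br	78.918337100	0.506900000
Br	80.916290600	0.493100000
Cd	105.906459000	0.012500000
Cd	107.904184000	0.008900000
Cd	109.903002100	0.124900000
Cd	110.904178100	0.128000000
Cd	111.902757800	0.241300000
Cd	112.904401700	0.122200000
Cd	113.903358500	0.287300000
Cd	115.904756000	0.074900000
I	126.904473000	1.000000000
Hg	195.965833000	0.001500000
Hg	197.966769000	0.099700000
Hg	198.968279900	0.168700000
Hg	199.968326000	0.231000000
Hg	200.970302300	0.131800000
Hg	201.970643000	0.298600000
Hg	203.973493900	0.068700000
Pb	203.973043600	0.014000000
Pb	205.974465300	0.241000000
Pb	206.975896900	0.221000000
Pb	207.976652100	0.524000000
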