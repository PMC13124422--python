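exposure	variant_id	effect_allele	other_allele	beta	se	pvalue	r2	f_statistic
SGLT2 inhibition	rs111510548	C	T	0.015	0.004	6.69E-05	0.000	14.06
SGLT2 inhibition	rs8057207	T	C	0.013	0.002	4.55E-08	0.000	42.25
SGLT2 inhibition	rs9926717	G	A	0.011	0.003	9.61E-06	0.000	13.44
SGLT2 inhibition	rs116943658	A	G	0.013	0.002	3.01E-07	0.000	42.25
SGLT2 inhibition	rs13334492	A	G	0.011	0.002	7.57E-07	0.000	30.25
SGLT2 inhibition	rs2070896	C	T	0.017	0.002	1.70E-12	0.000	72.25
SGLT2 inhibition	rs28641848	T	C	0.011	0.003	1.21E-05	0.000	13.44
SGLT2 inhibition	rs28692853	A	C	0.015	0.002	2.78E-10	0.000	56.25
SGLT2 inhibition	rs67464975	T	C	0.012	0.002	4.03E-07	0.000	36.00
SGLT2 inhibition	rs8050328	G	T	0.016	0.002	1.09E-11	0.000	64.00
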