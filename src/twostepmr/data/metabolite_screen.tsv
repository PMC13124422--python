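category	metabolite	or	or_ci_low	or_ci_high	pvalue
Amino acids	Alanine	1.40	1.14	1.72	1.17E-03
Amino acids	Glycine	1.41	1.16	1.72	4.76E-04
Amino acids	Histidine	0.73	0.59	0.89	2.46E-03
Amino acids	Isoleucine	0.71	0.58	0.87	8.37E-04
Cholesterol	Cholesterol in medium HDL	1.35	1.12	1.63	1.97E-03
Cholesterol	Cholesterol in small HDL	1.91	1.56	2.35	5.89E-10
Cholesterol	Cholesterol in very large HDL	0.59	0.47	0.75	1.52E-05
Cholines	Phosphatidylcholines	1.44	1.19	1.75	1.83E-04
Cholines	Phosphoglycerides	1.41	1.16	1.71	5.33E-04
Cholines	Total cholines	1.38	1.14	1.67	1.11E-03
Compounds	Total concentration of lipoprotein particles	1.52	1.25	1.85	2.10E-05
Compounds	Total triglycerides	1.33	1.09	1.63	4.61E-03
Esterified cholesterol	Cholesteryl esters in large LDL	1.33	1.08	1.63	6.56E-03
Esterified cholesterol	Cholesteryl esters in medium HDL	1.36	1.12	1.64	1.51E-03
Esterified cholesterol	Cholesteryl esters in small HDL	1.90	1.54	2.33	1.14E-09
Esterified cholesterol	Cholesteryl esters in very large HDL	0.62	0.50	0.78	5.52E-05
Fatty acids	Total fatty acids	1.40	1.14	1.71	1.36E-03
Fatty acids	Degree of unsaturation	0.76	0.63	0.93	6.39E-03
Fatty acids	Linoleic acid	1.39	1.14	1.70	1.36E-03
Fatty acids	Monounsaturated fatty acids	1.49	1.21	1.82	1.29E-04
Fatty acids	Omega-6 fatty acids	1.38	1.13	1.69	1.58E-03
Fatty acids	Polyunsaturated fatty acids	1.32	1.08	1.61	7.17E-03
Fatty acids	Saturated fatty acids	1.32	1.08	1.62	7.53E-03
Free cholesterol	Free cholesterol in medium HDL	1.29	1.07	1.55	7.83E-03
Free cholesterol	Free cholesterol in small HDL	1.78	1.45	2.18	2.28E-08
Free cholesterol	Free cholesterol in very large HDL	0.52	0.41	0.67	5.22E-07
Glycolysis	Citrate	0.72	0.58	0.88	1.38E-03
Ketone bodies	Acetone	0.64	0.51	0.80	6.77E-05
Ketone bodies	Glycoprotein acetyls	1.34	1.09	1.64	5.24E-03
Ketone bodies	Pyruvate	0.61	0.50	0.75	2.99E-06
Lipoprotein particles	Concentration of HDL particles	1.54	1.27	1.86	1.28E-05
Lipoprotein particles	Concentration of medium HDL particles	1.37	1.13	1.65	1.18E-03
Lipoprotein particles	Concentration of small HDL particles	1.90	1.55	2.33	9.28E-10
Lipoprotein particles	Concentration of very large HDL particles	0.61	0.48	0.78	7.55E-05
Phospholipids	Phospholipids in medium HDL	1.44	1.18	1.74	2.24E-04
Phospholipids	Phospholipids in medium LDL	1.32	1.08	1.62	8.07E-03
Phospholipids	Phospholipids in small HDL	1.84	1.50	2.26	4.26E-09
Phospholipids	Phospholipids in very large HDL	0.58	0.46	0.73	2.18E-06
Size&apo-LP	Average diameter for HDL particles	0.72	0.59	0.88	1.51E-03
Size&apo-LP	Average diameter for LDL particles	1.36	1.11	1.66	2.85E-03
Size&apo-LP	Average diameter for VLDL particles	1.32	1.09	1.60	4.58E-03
Size&apo-LP	Apolipoprotein A1	1.32	1.10	1.60	3.35E-03
Total lipids	Total lipids in large VLDL	1.31	1.07	1.60	7.53E-03
Total lipids	Total lipids in medium HDL	1.42	1.17	1.72	3.15E-04
Total lipids	Total lipids in small HDL	1.92	1.56	2.35	5.01E-10
Total lipids	Total lipids in very large HDL	0.59	0.46	0.74	7.32E-06
Triglycerides	Triglycerides in HDL	1.31	1.07	1.61	8.42E-03
Triglycerides	Triglycerides in large VLDL	1.37	1.12	1.67	1.86E-03
Triglycerides	Triglycerides in medium HDL	1.37	1.12	1.68	2.51E-03
Triglycerides	Triglycerides in medium VLDL	1.39	1.14	1.70	1.15E-03
Triglycerides	Triglycerides in small HDL	1.46	1.20	1.79	1.82E-04
Triglycerides	Triglycerides in small VLDL	1.37	1.12	1.67	2.04E-03
Triglycerides	Triglycerides in VLDL	1.35	1.11	1.64	3.07E-03
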