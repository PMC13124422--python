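exposure	mediator	outcome	total	total_p	step1	step1_p	step2	step2_p	mediation	proportion_pct
SGLT2 inhibition	Degree of unsaturation	Lung cancer	2.352	5.43E-06	-0.272	6.39E-03	0.118	1.32E-05	-0.032	-1.365
SGLT2 inhibition	Linoleic acid	Lung cancer	2.352	5.43E-06	0.330	1.36E-03	-0.127	2.67E-03	-0.042	-1.782
SGLT2 inhibition	Triglycerides in large VLDL	Lung cancer	2.352	5.43E-06	0.314	1.86E-03	-0.088	4.67E-03	-0.028	-1.175
SGLT2 inhibition	Monounsaturated fatty acids	Lung cancer	2.352	5.43E-06	0.398	1.29E-04	-0.101	4.86E-03	-0.040	-1.709
SGLT2 inhibition	Glycoprotein acetyls	Lung cancer	2.352	5.43E-06	0.291	5.24E-03	-0.114	6.74E-03	-0.033	-1.410
SGLT2 inhibition	Triglycerides in VLDL	Lung cancer	2.352	5.43E-06	0.299	3.07E-03	-0.082	7.33E-03	-0.025	-1.042
SGLT2 inhibition	Average diameter for LDL particles	Lung cancer	2.352	5.43E-06	0.306	2.85E-03	-0.154	9.61E-03	-0.047	-2.004
SGLT2 inhibition	Total lipids in very large HDL	Colorectal cancer	1.186	6.38E-04	-0.534	7.32E-06	0.107	3.53E-07	-0.057	-4.818
SGLT2 inhibition	Cholesterol in very large HDL	Colorectal cancer	1.186	6.38E-04	-0.522	1.52E-05	0.106	3.90E-07	-0.055	-4.665
SGLT2 inhibition	Phospholipids in very large HDL	Colorectal cancer	1.186	6.38E-04	-0.544	2.18E-06	0.105	4.19E-07	-0.057	-4.816
SGLT2 inhibition	Concentration of very large HDL particles	Colorectal cancer	1.186	6.38E-04	-0.492	7.55E-05	0.101	1.15E-06	-0.050	-4.190
SGLT2 inhibition	Cholesteryl esters in very large HDL	Colorectal cancer	1.186	6.38E-04	-0.472	5.52E-05	0.101	1.57E-06	-0.048	-4.020
SGLT2 inhibition	Free cholesterol in very large HDL	Colorectal cancer	1.186	6.38E-04	-0.648	5.22E-07	0.094	3.44E-06	-0.061	-5.136
SGLT2 inhibition	Degree of unsaturation	Colorectal cancer	1.186	6.38E-04	-0.272	6.39E-03	0.101	1.71E-05	-0.027	-2.316
SGLT2 inhibition	Average diameter for HDL particles	Colorectal cancer	1.186	6.38E-04	-0.322	1.51E-03	0.080	7.47E-05	-0.026	-2.172
SGLT2 inhibition	Polyunsaturated fatty acids	Colorectal cancer	1.186	6.38E-04	0.275	7.17E-03	0.103	2.84E-04	0.028	2.388
SGLT2 inhibition	Total lipids in small HDL	Colorectal cancer	1.186	6.38E-04	0.650	5.01E-10	-0.118	8.36E-04	-0.077	-6.467
SGLT2 inhibition	Concentration of small HDL particles	Colorectal cancer	1.186	6.38E-04	0.642	9.28E-10	-0.126	9.97E-04	-0.081	-6.821
SGLT2 inhibition	Cholesteryl esters in small HDL	Colorectal cancer	1.186	6.38E-04	0.640	1.14E-09	-0.105	1.89E-03	-0.067	-5.666
SGLT2 inhibition	Cholesterol in small HDL	Colorectal cancer	1.186	6.38E-04	0.649	5.89E-10	-0.119	1.92E-03	-0.077	-6.512
SGLT2 inhibition	Phospholipids in small HDL	Colorectal cancer	1.186	6.38E-04	0.611	4.26E-09	-0.099	2.90E-03	-0.060	-5.100
SGLT2 inhibition	Omega-6 fatty acids	Colorectal cancer	1.186	6.38E-04	0.324	1.58E-03	0.078	8.48E-03	0.025	2.131
SGLT2 inhibition	Degree of unsaturation	Skin cancer	1.804	5.86E-11	-0.272	6.39E-03	0.115	3.75E-12	-0.031	-1.734
SGLT2 inhibition	Glycoprotein acetyls	Skin cancer	1.804	5.86E-11	0.291	5.24E-03	-0.085	2.26E-03	-0.025	-1.371
SGLT2 inhibition	Acetone	Skin cancer	1.804	5.86E-11	-0.449	6.77E-05	-0.206	9.03E-03	0.092	5.127
SGLT2 inhibition	Triglycerides in medium HDL	Brain tumor	-2.754	1.22E-02	0.313	2.51E-03	-0.233	3.65E-04	-0.073	2.648
SGLT2 inhibition	Triglycerides in HDL	Brain tumor	-2.754	1.22E-02	0.273	8.42E-03	-0.215	8.27E-04	-0.059	2.131
SGLT2 inhibition	Triglycerides in VLDL	Brain tumor	-2.754	1.22E-02	0.299	3.07E-03	-0.193	9.17E-03	-0.058	2.095
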