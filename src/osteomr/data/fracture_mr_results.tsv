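trait	exposure_type	n_markers	or_ivw	lo_ivw	hi_ivw	p_ivw	power_pct	egger_intercept	egger_lo	egger_hi	egger_p
Decreased femoral neck BMD	quantitative	43	1.55	1.48	1.63	1.5e-68	100	-0.0010	-0.011	0.008	0.83
Decreased lumbar spine BMD	quantitative	40	1.43	1.37	1.50	2.3e-55	100	0.0050	-0.006	0.014	0.93
Earlier menopause	quantitative	54	1.10	1.00	1.21	0.05	100	0.0007	-0.006	0.007	0.83
Rheumatoid arthritis	binary	30	1.01	1.00	1.02	0.14	100	0.0099	0.003	0.017	0.005
Type 1 diabetes	binary	19	1.00	1.00	1.01	0.57	100	0.0028	-0.004	0.010	0.39
Inflammatory bowel disease	binary	151	1.00	1.00	1.01	0.92	100	0.0003	-0.003	0.004	0.86
Decreased thyroid stimulating hormone	quantitative	20	0.99	0.94	1.04	0.78	100	0.0050	-0.019	0.009	0.47
Increased homocysteine levels	quantitative	13	0.98	0.92	1.05	0.60	100	0.0134	0.001	0.026	0.03
Decreased grip strength	quantitative	15	2.14	1.13	4.04	0.01	56	0.1070	0.011	0.203	0.03
Late puberty	quantitative	106	1.06	1.00	1.13	0.04	92	0.0036	-0.002	0.009	0.21
Increased fasting glucose levels	quantitative	35	1.04	0.97	1.12	0.24	100	-0.0083	-0.014	-0.002	0.01
Coronary heart disease	binary	38	1.00	0.99	1.02	0.76	100	0.0028	-0.007	0.013	0.57
Type 2 diabetes	binary	38	0.99	0.99	1.01	0.37	100	-0.0089	-0.016	-0.002	0.02
Decreased vitamin D levels	quantitative	4	0.84	0.70	1.02	0.07	87	-0.0143	-0.103	0.074	0.56
Decreased dairy calcium intake	quantitative	1	1.01	0.80	1.23	0.94	NA	NA	NA	NA	NA
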