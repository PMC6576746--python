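template_id	candidate_structure	protein_key	protein_name	p_value
1SO2	5U09	P21554	Cannabinoid receptor	4.13e-4
1SO2	1XU9	P28845	Corticosteroid 11-beta dehydrogenase	4.16e-5
1SO2	3HX3	P12271	Retinaldehyde-binding protein 1	5.42e-4
1SO2	1R5L	P49638	alpha-tocopherol transfer protein	3.40e-5
1SO2	3VW7	P25116	Proteinase-activated receptor 1	6.86e-5
1SO2	3SOA	Q9UQM7	Calcium/calmodulin-dependent kinase (CAMK2A)	3.66e-4
1SO2	1UW5	Q00169	Phosphatidylinositol transfer protein	4.36e-4
1SO2	3K1Z	Q9BSH5	Haloacid dehalogenase-like hydrolase domain-containing protein 3	2.63e-4
1SO2	4Q6R	O95470	Sphingosine-1-phosphate lyase 1	3.62e-4
1SO2	4OQA	P09874	Poly [ADP-ribose] polymerase 1	3.47e-6
1SO2	2OBD	P11597	Cholesteryl ester transfer protein	1.43e-3
1SO2	2CW6	P35914	Hydroxymethylglutaryl-CoA lyase	1.36e-3
1SO2	4OQV	Q02127	Dihydroorotate dehydrogenase	3.29e-4
1SO2	5KDI	Q96JA3	Pleckstrin homology domain-containing family A protein	9.93e-4
1SO2	4FC7	Q9NUI1	Peroxisomal 2,4-dienoyl-CoA reductase	1.36e-3
1SO2	4OTP	Q9BRS2	Serine/threonine protein kinase (RIOK1)	1.45e-3
1SO2	5HZ8	P15090	Fatty acid-binding protein	1.08e-3
1SO2	4P8V	Q15782	Chitinase-3-like protein 2	6.65e-4
1SO2	5FYQ	P62826	NAD-dependent protein deacetylase	2.64e-4
1SO2	2ONI	Q96PU5	E3 ubiquitin-protein ligase NEDD4-like protein	1.03e-3
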