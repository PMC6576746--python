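protein_key	chemical_key	score
P21554	milrinone	-7.4
P21554	anagrelide	-7.3
P21554	levosimendan	-9.0
P21554	amrinone	-7.1
P21554	enoximone	-7.6
P28845	milrinone	-8.2
P28845	anagrelide	-7.6
P28845	levosimendan	-8.8
P28845	amrinone	-7.1
P28845	enoximone	-7.5
P12271	milrinone	-7.3
P12271	anagrelide	-7.6
P12271	levosimendan	-8.8
P12271	amrinone	-7.0
P12271	enoximone	-7.6
P49638	milrinone	-7.2
P49638	anagrelide	-7.8
P49638	levosimendan	-8.6
P49638	amrinone	-6.6
P49638	enoximone	-7.1
P25116	milrinone	-7.7
P25116	anagrelide	-7.8
P25116	levosimendan	-8.4
P25116	amrinone	-7.2
P25116	enoximone	-7.5
Q9UQM7	milrinone	-7.6
Q9UQM7	anagrelide	-6.9
Q9UQM7	levosimendan	-8.0
Q9UQM7	amrinone	-7.0
Q9UQM7	enoximone	-6.9
Q00169	milrinone	-7.1
Q00169	anagrelide	-6.8
Q00169	levosimendan	-8.0
Q00169	amrinone	-6.9
Q00169	enoximone	-6.8
Q9BSH5	milrinone	-8.2
Q9BSH5	anagrelide	-8.4
Q9BSH5	levosimendan	-8.0
Q9BSH5	amrinone	-7.7
Q9BSH5	enoximone	-7.5
O95470	milrinone	-6.4
O95470	anagrelide	-7.3
O95470	levosimendan	-8.0
O95470	amrinone	-6.4
O95470	enoximone	-6.6
P09874	milrinone	-7.1
P09874	anagrelide	-7.8
P09874	levosimendan	-7.8
P09874	amrinone	-7.0
P09874	enoximone	-7.0
P11597	milrinone	-7.0
P11597	anagrelide	-7.2
P11597	levosimendan	-7.8
P11597	amrinone	-6.4
P11597	enoximone	-6.8
P35914	milrinone	-6.5
P35914	anagrelide	-7.3
P35914	levosimendan	-7.8
P35914	amrinone	-6.3
P35914	enoximone	-7.7
Q02127	milrinone	-8.0
Q02127	anagrelide	-6.7
Q02127	levosimendan	-7.8
Q02127	amrinone	-7.0
Q02127	enoximone	-8.2
Q96JA3	milrinone	-7.3
Q96JA3	anagrelide	-7.2
Q96JA3	levosimendan	-7.6
Q96JA3	amrinone	-6.6
Q96JA3	enoximone	-7.1
Q9NUI1	milrinone	-6.6
Q9NUI1	anagrelide	-7.0
Q9NUI1	levosimendan	-7.6
Q9NUI1	amrinone	-6.3
Q9NUI1	enoximone	-6.5
Q9BRS2	milrinone	-7.0
Q9BRS2	anagrelide	-7.2
Q9BRS2	levosimendan	-7.6
Q9BRS2	amrinone	-6.7
Q9BRS2	enoximone	-6.7
P15090	milrinone	-7.1
P15090	anagrelide	-7.9
P15090	levosimendan	-7.5
P15090	amrinone	-6.9
P15090	enoximone	-6.7
Q15782	milrinone	-7.3
Q15782	anagrelide	-6.9
Q15782	levosimendan	-7.5
Q15782	amrinone	-6.6
Q15782	enoximone	-6.7
P62826	milrinone	-6.2
P62826	anagrelide	-6.7
P62826	levosimendan	-7.4
P62826	amrinone	-5.9
P62826	enoximone	-6.2
Q96PU5	milrinone	-7.0
Q96PU5	anagrelide	-6.6
Q96PU5	levosimendan	-7.2
Q96PU5	amrinone	-6.7
Q96PU5	enoximone	-5.7
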