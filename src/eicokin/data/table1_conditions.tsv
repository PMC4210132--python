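symbol	AJ_control	AJ_DDC	B6_control	B6_DDC	PWD_control	PWD_DDC
PTGS1	1.00	2.13	1.00	1.41	1.00	2.09
ALOX5	1.00	1.00	1.00	1.00	1.00	1.00
PTGDS	1.00	1.00	1.00	1.00	1.00	1.00
PSTAT3	1.00	1.41	1.00	1.42	1.00	2.03
PKCD	1.00	4.30	1.00	4.48	1.00	3.85
GPX	1.00	6.51	1.00	11.70	1.00	19.42
PLA2	1.00	1.90	1.00	2.09	1.00	1.98
ALOX5AP	1.00	4.81	1.00	6.30	1.00	14.23
ALOX15	1.00	1.00	1.00	1.00	1.00	1.00
PC	269.00	206.00	249.00	209.00	266.00	255.00
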