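subfamily	top_gene	car_rank
AP-2	TFAP2C	1
Kruppel-like factors	KLF4	1
FOXA	FOXA1	1
Group B	SOX2	1
Two zinc-finger GATA factors	GATA6	2
Spi-like factors	SPI1	5
Arnt-like factors	ARNTL2	76
POU5 (Oct-3/4-like factors)	POU5F1	197
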