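# dysbiome-coefficients-v1	compartment=gut
term	b1	b2
Intercept	-0.469294	5.715458
ShannonIndex	0.05286898	-2.57213563
Campylobacter	0.183625542	0.006264282
Fenollaria	0.1631794	-0.4952786
Ezakiella	0.19868003	-0.08232344
Enterococcus	0.5214449	0.6635925
Blautia	-1.217537	-0.795908
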