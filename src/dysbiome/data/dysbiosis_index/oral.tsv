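# dysbiome-coefficients-v1	compartment=oral
term	b1	b2
Intercept	3.639385	15.535322
Pasteurellaceae_uncl	-0.4745086	-2.3936493
Alloprevotella	-0.384223	-1.086375
Anaerovoracaceae_ge	-0.5694409	-1.0899032
Centipeda	-0.5507802	-1.7643090
Fusobacterium	-0.2282283	-1.2268803
Streptococcus	0.3062403	-0.1848412
Veillonella	-0.1108369	-0.9535763
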