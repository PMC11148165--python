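# dysbiome-coefficients-v1	compartment=lung
term	b1	b2
Intercept	6.314866	11.631919
ShannonIndex	-2.064372	-3.663621
Porphyromonas	-0.2249019	-1.0790556
Peptostreptococcus	0.0226691	0.6814249
Gemella	0.03023337	-0.23503918
Actinomyces	0.1083389	-0.6340821
Rothia	0.3937065	0.5838788
Treponema	-1.120237	-1.605860
Bergeyella	-0.1974596	-0.6481431
Alloprevotella	-0.3517737	-0.7556098
Solobacterium	-0.2284961	-0.8208410
Atopobium	-0.2868991	-0.3039660
Neisseriaceae_uncl	-0.3906575	-2.6100531
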