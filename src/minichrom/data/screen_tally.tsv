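# kernel-screen fate tallies: ~10,000 kernels screened for 9-Bic-1 breakage,
# 1412 with breakage signs examined by FISH; six of the ten recovered mini
# chromosomes have B-arm breakpoints attributing them to B chromosome breakage
kernels_screened	10000
kernels_with_breakage_signs	1412
lost	1391
isochromosome	10
translocation	1
mini_chromosome	10
other	0
b_derived_minis	6
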