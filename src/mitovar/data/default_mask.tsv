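# Low-complexity / ambiguous mtDNA regions excluded from heteroplasmy calling.
# BED-like: chrom, 0-based start, end (half-open); 1-based inclusive spans are
# 302-316, 513-526, 566-573, 3106-3107, 16181-16194.
chrM	301	316
chrM	512	526
chrM	565	573
chrM	3105	3107
chrM	16180	16194
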