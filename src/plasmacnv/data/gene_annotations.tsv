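gene	chrom	start	end
FGFR1	chr8	38268656	38326352
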