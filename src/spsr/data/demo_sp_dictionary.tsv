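peptide	ec	taxon_rank	taxon_name
NSISISGYH	5.4.99.2
ISISGYHMQEAG	5.4.99.2
MKLAVNDER	6.1.1.1
WQHTPLYVD	6.1.1.4
GFDETRWNA	1.1.1.1
HPYKCMSTQ	2.7.7.7
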