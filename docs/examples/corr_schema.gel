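# Schema for importing a weighted gene-correlation edge list.
nodetype gene_nt(id: string);
linktype corr_lt[weight: double];
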