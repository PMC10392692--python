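>asyn_ctail alpha-synuclein C-terminal tail, residues 101-140
GKNEEGAPQEGILEDMPVDPDNEAYEMPSEEGYQDYEPEA
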