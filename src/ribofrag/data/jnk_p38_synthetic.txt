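# Synthetic stand-in for a curated JNK/p38-pathway-associated gene list.
# These are placeholder ids matching the simulator's gene naming; real
# analyses should supply their own curated list via read_geneset().
g0000
g0001
g0002
g0003
g0004
g0005
g0006
g0007
g0008
g0009
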