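# Synthetic stand-in for a curated interferon-stimulated gene list.
# Placeholder ids matching the simulator's gene naming; supply a real
# curated list via read_geneset() for actual analyses.
g0010
g0011
g0012
g0013
g0014
g0015
g0016
g0017
g0018
g0019
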