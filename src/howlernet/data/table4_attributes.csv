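metric,continuous,fragments
No. of monkeys,15,18
No. of plant species,27,30
Nestedness (NODF-metric),51.41,62.42
Links per species,3.76,4.08
Connectance (C),0.39,0.36
Interaction diversity,5.06,5.27
Resource selectivity (H2'),0.28,0.22
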