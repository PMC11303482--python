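>ZEB1_synthetic
A [ 5 85 5 5 5 5 5 ]
C [ 85 5 85 85 5 5 5 ]
G [ 5 5 5 5 5 85 5 ]
T [ 5 5 5 5 85 5 85 ]
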