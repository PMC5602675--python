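1 8 10 18 20 29 30 32 37 41 53 54 55 63 72 88 96 102 110
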