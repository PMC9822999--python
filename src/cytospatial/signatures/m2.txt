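MRC1
CD163
MSR1
STAB1
IL4R
TGFB1
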