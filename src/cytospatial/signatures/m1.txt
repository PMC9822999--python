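TNF
IL1B
IL6
CXCL11
NOS2
IL12B
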