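CXCL9
CXCL10
CCL2
CCL4
CCL5
CCL17
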