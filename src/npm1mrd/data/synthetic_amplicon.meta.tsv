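key	value
hotspot_start	100
hotspot_end	130
coding_offset	761
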