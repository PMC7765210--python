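stage	day	ja_level	ja_sd
vegetative	14	389	8
apical_floral_induction	21	217	13
flowering	28	37.5	1.8
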