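name	start_res	end_res	parent
atpase	5	80
core	90	270
greek_key	100	140	core
whd	150	220	core
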