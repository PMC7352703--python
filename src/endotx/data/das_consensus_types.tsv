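source	event_type	count
rMATS	SE	8
rMATS	A5SS	19
rMATS	A3SS	25
rMATS	MXE	9
rMATS	RI	131
SUPPA	SE	8
SUPPA	A5SS	11
SUPPA	A3SS	24
SUPPA	MXE	3
SUPPA	RI	129
SUPPA	AF	33
SUPPA	AL	6
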