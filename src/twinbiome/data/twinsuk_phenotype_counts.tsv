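abo	secretor	sex	count
A	S	F	405
A	S	M	35
A	NS	F	137
A	NS	M	14
A	unknown	F	12
A	unknown	M	3
AB	S	F	20
AB	S	M	6
AB	NS	F	9
AB	NS	M	3
AB	unknown	F	2
AB	unknown	M	0
B	S	F	96
B	S	M	7
B	NS	F	30
B	NS	M	3
B	unknown	F	2
B	unknown	M	2
O	S	F	449
O	S	M	41
O	NS	F	175
O	NS	M	22
O	unknown	F	27
O	unknown	M	3
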