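SESSION	ONLINE
1A	48,8
1B	58,5
2A	67,7
2B	61,0
3A	64,4
4A	48,8
4B	56,1
5A	92,7
5B	82,9
6A	51,2
6B	78,1
7A	51,2
7B	41,5
8A	70,7
8B	63,4
9A	58,5
9B	65,9
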