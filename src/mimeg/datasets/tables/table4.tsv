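SESSION	STFT	Morlet	PSD	FBCSP	SSD	CSP	SSD+CSP	CSP+STFT	CSP+Morlet	CSP+PSD
1A	74,0	78,9	79,5	97,5	82,9	95,1	94,4	95,7	94,4	93,8
1B	83,8	86,3	80,7	99,4	80,2	98,2	99,4	95,7	96,3	92,6
2A	71,2	69,2	73,8	70,0	70,4	73,2	73,1	72,5	73,2	73,8
2B	72,1	71,8	72,3	61,5	64,3	71,5	75,2	67,1	67,1	67,1
3A	85,5	86,5	87,5	70,2	81,5	76,9	79,3	86,1	86,5	80,8
4A	78,9	80,2	80,2	83,2	72,9	88,2	85,1	85,7	87,6	87,0
4B	82,6	80,7	85,7	76,3	53,0	87,5	85,7	82,0	83,2	82,6
5A	67,7	70,2	71,4	73,3	53,0	70,2	68,3	72,1	76,4	73,3
5B	63,9	67,0	63,3	69,6	67,8	67,8	66,5	63,4	65,2	66,5
6A	91,3	91,3	88,8	93,2	87,7	90,7	93,2	88,8	90,7	87,6
6B	78,2	85,7	80,7	88,2	85,2	83,2	85,1	84,5	86,3	78,2
7A	71,5	72,7	73,9	78,3	64,1	85,1	79,5	85,1	86,4	85,1
7B	70,2	77,6	74,5	79,5	70,3	84,4	83,2	86,9	87,5	78,2
8A	73,9	75,2	73,9	68,9	79,2	65,2	80,8	63,9	67,6	64,5
8B	85,7	86,3	84,5	83,3	82,7	74,5	88,2	71,4	70,7	65,8
9A	60,5	70,1	68,3	64,6	49,3	58,4	69,5	57,2	62,1	59,0
9B	80,0	80,8	83,2	63,3	62,9	67,6	75,1	77,0	77,6	74,5
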