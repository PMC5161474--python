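SESSION	STFT	Morlet	PSD	FBCSP	SSD	CSP	SSD+CSP	CSP+STFT	CSP+Morlet	CSP+PSD
1A	75,3	70,3	69,2	76,6	70,4	82,7	82,8	80,4	81,5	79,0
1B	75,2	71,5	74,0	76,5	60,3	75,1	65,2	74,0	70,4	70,4
2A	59,4	63,4	70,2	54,1	66,4	66,3	67,5	59,4	65,0	52,9
2B	70,4	79,0	69,2	67,7	51,8	65,2	66,5	66,5	70,4	66,6
3A	69,0	74,1	73,8	68,6	62,9	59,6	77,9	57,4	58,4	59,4
4A	76,5	75,2	79,0	72,9	60,4	75,1	76,8	70,4	71,6	67,9
4B	58,1	63,0	56,8	64,1	58,0	79,0	76,5	76,5	79,1	72,8
5A	80,2	77,7	68,0	77,6	81,5	69,3	80,2	75,3	77,9	74,1
5B	79,0	82,9	77,9	74,2	82,9	86,6	90,2	89,0	84,1	77,9
6A	66,6	67,9	71,8	65,7	56,6	67,7	75,2	74,3	71,5	75,3
6B	86,5	91,4	91,4	86,4	59,4	84,0	90,2	87,7	88,9	86,5
7A	59,3	65,6	62,9	57,1	65,5	65,4	66,6	63,1	61,9	61,8
7B	49,2	59,0	56,5	56,5	35,7	61,8	59,3	65,4	65,5	65,6
8A	55,4	64,0	66,5	57,9	45,5	60,4	65,4	65,4	62,9	67,9
8B	64,6	61,9	61,8	60,7	61,6	57,0	65,7	65,7	60,7	64,6
9A	66,8	59,3	61,7	65,4	53,1	69,0	76,5	76,6	73,0	79,0
9B	49,4	55,4	59,2	44,4	65,4	53,3	70,4	64,3	63,0	55,6
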