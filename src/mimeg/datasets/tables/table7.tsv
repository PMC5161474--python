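SESSION	STFT	Morlet	PSD	FBCSP	SSD	CSP	SSD+CSP	CSP+STFT	CSP+Morlet	CSP+PSD
1A	60,5	56,8	58,0	54,3	64,2	71,6	69,1	69,1	71,6	69,1
1B	69,1	71,6	65,4	61,7	69,1	74,1	72,8	71,6	69,1	79,0
2A	52,6	55,1	52,6	53,9	44,9	50,0	50,0	50,0	50,0	50,0
2B	54,6	58,4	54,6	59,7	35,1	55,8	55,8	55,8	55,8	55,8
4A	67,9	74,1	77,8	72,8	58,0	81,5	75,3	79,0	81,5	81,5
4B	70,4	75,3	72,8	59,3	56,8	69,1	69,1	72,8	75,3	66,7
5A	81,5	80,3	82,7	71,6	82,7	82,7	84,0	84,0	81,5	77,8
5B	81,5	84,0	85,2	91,4	82,7	82,7	80,2	82,7	85,2	81,5
6A	85,2	86,4	84,0	84,0	59,3	70,4	82,7	80,3	81,5	72,8
6B	66,7	66,7	71,6	81,5	69,1	70,4	66,7	65,4	67,9	64,2
7A	56,8	67,9	61,7	58,0	56,8	58,0	64,2	63,0	56,8	58,0
7B	58,0	64,2	58,0	63,0	44,4	61,7	56,8	63,0	66,7	55,6
8A	63,0	64,2	63,0	54,3	55,6	58,0	64,2	54,3	55,6	51,9
8B	55,6	60,5	60,5	60,5	55,6	64,2	64,2	61,7	63,0	59,3
9A	66,7	69,1	65,4	71,6	63,0	60,5	76,5	64,2	65,4	63,0
9B	65,4	64,2	69,1	69,1	75,3	75,3	72,8	70,4	79,0	75,3
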