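CLASSIFIER	CSP	STFT
RBF_SVM	69,56	65,23
LINEAR_SVM	70,39	65,46
NAIVE_BAYES	67,42	61,70
LDA	70,07	67,13
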