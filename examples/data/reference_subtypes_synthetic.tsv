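subtype	ESC	PRC2	MYC+	ERG-fusion	PTEN-	P53-	Proliferation	AR	Mesenchyme	Cytokine	RAS	ProNeural	NeuroEndocrine	EMT	Inflammation
BP-E/P/Pr	1	-1	0.5	0	1	0.5	1	0	-0.5	-0.5	0	0	0	0	-0.5
BP-ERG	0	-0.5	0	1	0	0	0.5	0.5	-0.5	0	-0.5	0	0	0	0
GP1	-0.5	0.5	-0.5	0	-0.5	0	-1	0	1	0.5	0.5	0	0	0.5	0.5
GP2	-1	1	-1	-0.5	-0.5	-0.5	-0.5	0.5	0.5	1	0.5	0.5	0.5	0.5	1
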