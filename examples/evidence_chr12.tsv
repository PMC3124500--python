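family	chromosome	start_Mb	end_Mb	p
AXBXA	12	113.270	120.968	0.000525
BXH	12	110.500	114.345	0.000089
CXB	12	113.000	118.500	0.000692
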