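sample_id	donor_id	region
D1_FL	D1	FL
D1_TL	D1	TL
D1_PL	D1	PL
D1_OL	D1	OL
D1_CB	D1	CB
D1_BS	D1	BS
D1_THA_HT	D1	THA/HT
D1_OC	D1	OC
D1_CC	D1	CC
D1_VT	D1	VT
D1_HIP	D1	HIP
D1_AN	D1	AN
D1_OB_OT	D1	OB/OT
D2_FL	D2	FL
D2_TL	D2	TL
D2_PL	D2	PL
D2_OL	D2	OL
D2_CB	D2	CB
D2_THA_HT	D2	THA/HT
D2_OC	D2	OC
D2_CC	D2	CC
D2_VT	D2	VT
D2_HIP	D2	HIP
D2_AN	D2	AN
D2_OB_OT	D2	OB/OT
D3_FL	D3	FL
D3_TL	D3	TL
D3_PL	D3	PL
D3_OL	D3	OL
D3_CB	D3	CB
D3_BS	D3	BS
D3_THA_HT	D3	THA/HT
D3_OC	D3	OC
D3_CC	D3	CC
D3_VT	D3	VT
D3_HIP	D3	HIP
D3_AN	D3	AN
D3_OB_OT	D3	OB/OT
D4_FL	D4	FL
D4_TL	D4	TL
D4_PL	D4	PL
D4_OL	D4	OL
D4_CB	D4	CB
D4_BS	D4	BS
D4_THA_HT	D4	THA/HT
D4_OC	D4	OC
D4_CC	D4	CC
D4_VT	D4	VT
D4_HIP	D4	HIP
D4_AN	D4	AN
D5_FL	D5	FL
D5_TL	D5	TL
D5_PL	D5	PL
D5_OL	D5	OL
D5_CB	D5	CB
D5_BS	D5	BS
D5_OC	D5	OC
D5_CC	D5	CC
D5_VT	D5	VT
D5_HIP	D5	HIP
D5_AN	D5	AN
D5_OB_OT	D5	OB/OT
D6_FL	D6	FL
D6_TL	D6	TL
D6_PL	D6	PL
D6_OL	D6	OL
D6_CB	D6	CB
D6_BS	D6	BS
D6_THA_HT	D6	THA/HT
D6_OC	D6	OC
D6_CC	D6	CC
D6_VT	D6	VT
D6_HIP	D6	HIP
D6_AN	D6	AN
D7_FL	D7	FL
D7_TL	D7	TL
D7_PL	D7	PL
D7_OL	D7	OL
D7_CB	D7	CB
D7_BS	D7	BS
D7_THA_HT	D7	THA/HT
D7_OC	D7	OC
D7_CC	D7	CC
D7_VT	D7	VT
D7_HIP	D7	HIP
D7_AN	D7	AN
D7_OB_OT	D7	OB/OT
D8_FL	D8	FL
D8_TL	D8	TL
D8_PL	D8	PL
D8_OL	D8	OL
D8_BS	D8	BS
D8_THA_HT	D8	THA/HT
D8_OC	D8	OC
D8_CC	D8	CC
D8_VT	D8	VT
D8_HIP	D8	HIP
D8_AN	D8	AN
D8_OB_OT	D8	OB/OT
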