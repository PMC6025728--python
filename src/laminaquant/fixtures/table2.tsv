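gene	pair	sizes_bp	t3_extension_bp	predicted_transcripts	detected_transcripts	confirmed_junctions	rtpcr_negative
Clcc1	pr.1+pr.9	208	26	NM_145543	NM_145543	ex.1a_ex.3	no
Clcc1	pr.2+pr.9	181,252	26	NM_145543,NM_001177771,XM_006501416,XM_011240107	NM_145543,XM_006501416	ex.1a/1b_ex.3	no
Clcc1	pr.3+pr.9	220	26	NM_001177771,XM_006501416,XM_011240107	XM_006501416	ex.1b_ex.3	no
Clcc1	pr.4+pr.9	203	26	NM_001177771,NM_001177770,XM_006501416,XM_011240107	XM_006501416	ex.1b_ex.3	no
Clcc1	pr.5+pr.9	172	26	NM_001177771,NM_001177770,XM_006501416,XM_011240107	XM_006501416	ex.1b_ex.3	no
Clcc1	pr.6+pr.9	293	26	NM_001177770,XM_011240107	none	none	yes
Clcc1	pr.7+pr.9	300	26	NM_001177771,novel	novel	ex.2_ex.3	no
Clcc1	pr.2+pr.8	199,270	26	NM_001177771	none	none	yes
Clcc1	pr.3+pr.8	238	26	NM_001177771	none	none	yes
Clcc1	pr.4+pr.8	221	26	NM_001177771	none	none	yes
Clcc1	pr.6+pr.8	453	26	none	none	none	yes
Clcc1	pr.7+pr.8	159	26	NM_001177771,novel	novel	ex.2	no
Clcc1	pr.10+pr.11	432	26	all	all	ex.4_ex.5_ex.6	no
Pnkd	pr.1+pr.2	246	26	NM_025580,NM_001039509	NM_001039509	ex.2_ex.3	no
Pnkd	pr.3+pr.4	289	26	NM_025580	none	none	yes
Pnkd	pr.5+pr.6	167	26	NM_019999	NM_019999	ex.5	no
Pnkd	pr.5+pr.7	282	26	NM_019999	NM_019999	ex.5_ex.6	no
Pnkd	pr.8+pr.9	360	26	all	all	3utr	no
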