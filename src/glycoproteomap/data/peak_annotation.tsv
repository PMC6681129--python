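peak_id	structure_labels	dominant_index
GP1	A2	0
GP2	FA2	0
GP3	A2(6)BG1	0
GP4	FA2B	0
GP5	M5	0
GP6	A2(6)G1 + A2(3)G1	0
GP7	M6	0
GP8	A2G2	0
GP9	A2BG2 + M7	0
GP10	FA2G2	0
GP11	FA2BG2	0
GP12	A2(6)G1S(3)1	0
GP13	FA2G1S(6)1 + M8	0
GP14	A2G2S(6)1 + A2G2S(3)1	0
GP15	FA2G2S(6)1 + FA2G2S(3)1	0
GP16	FA2BG2S(3)1 + FA2BG2S(6)1	0
GP17	A3G3S(3)1	0
GP18	M9	0
GP19	A2G2S(3,6)2 + A2G2S(6,6)2 + A2G2S(3,3)2	0
GP20	FA2G2S(3,6)2 + FA2G2S(3,3)2	0
GP21	FA2BG2S(3,6)2 + FA2BG2S(6,6)2 + FA2BG2S(3,3)2	0
GP22	A3G3S(3,6)2	0
GP23	A3G3S(3,3)2	0
GP24	A3G3S(3,3,3)3	0
GP25	A3G3S(3,3,6)3	0
GP26	FA3G3S(3,3,3)3	0
GP27	A4G3S(3,3,3)3	0
GP28	A3G3S(3,6,6)3	0
GP29	A3F1G3S(3,3,3)3 + A3F1G3S(3,3,6)3	0
GP30	A4G4S(3,3,3)3	0
GP31	A4G4S(3,3,6)3	0
GP32	A4F1G3S(3,3,3)3 + A4F1G3S(3,3,6)3 + A4F1G3S(3,6,6)3	0
GP33	A4G4S(3,3,3,3)4	0
GP34	A4G4S(3,3,3,6)4	0
GP35	A4F1G4S(3,3,3,3)4	0
GP36	A4F1G4S(3,3,3,6)4	0
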