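sample_id,group,method,rank,genome_label,percent_identity
MR_LB_pH8,A,reduced_rep,1,Geobacillus thermodenitrificans strain OS27,99.64
MR_LB_pH8,A,wgs,1,Geobacillus thermodenitrificans strain KCTC3902,
MR_LB_pH8,A,rrna16s,1,Geobacillus thermodenitrificans strain KCTC3902,100.00
MR_LB_pH8,A,rrna16s,2,Geobacillus sp. PA-3 GEPA3,100.00
MR_LB_pH8,A,rrna16s,3,Geobacillus thermodenitrificans NG80-2,100.00
B_mud_LB_pH8,A,reduced_rep,1,Geobacillus vulcani PSS1,99.40
B_mud_LB_pH8,A,wgs,1,Geobacillus vulcani PSS1,
B_mud_LB_pH8,A,rrna16s,1,Geobacillus vulcani PSS1,100.00
B_mud_LB_pH8,A,rrna16s,2,Geobacillus sp. FW23,100.00
NFOSA3,B,reduced_rep,1,Geobacillus galactosidasius strain DSM 18751,98.85
NFOSA3,B,wgs,1,Geobacillus galactosidasius strain DSM 18751,
NFOSA3,B,rrna16s,1,Geobacillus galactosidasius strain DSM 18751,100.00
DSP4a,B,reduced_rep,1,Geobacillus lituanicus strain N-3,98.55
DSP4a,B,wgs,1,Geobacillus lituanicus strain N-3,
DSP4a,B,rrna16s,1,Geobacillus stearothermophilus strain FHS-PHGT51,100.00
DSP4a,B,rrna16s,2,Geobacillus stearothermophilus strain DSM 458,100.00
DSP4a,B,rrna16s,3,Geobacillus stearothermophilus strain GS27,100.00
DSP4a,B,rrna16s,4,Geobacillus sp. Sah69,100.00
DSP4a,B,rrna16s,5,Geobacillus stearothermophilus ATCC 12980,100.00
DSP4a,B,rrna16s,6,Geobacillus stearothermophilus ATCC 7953,100.00
CHMud_LB_pH8,B,reduced_rep,1,Anoxybacillus sp. 103,98.43
CHMud_LB_pH8,B,wgs,1,Anoxybacillus sp. 103,
CHMud_LB_pH8,B,rrna16s,1,Anoxybacillus kamchatkensis strain G10,100.00
Efil_LB_pH6.8_a,B,reduced_rep,1,Anoxybacillus ayderensis strain AB04,98.40
Efil_LB_pH6.8_a,B,wgs,1,Anoxybacillus ayderensis strain AB04,
Efil_LB_pH6.8_a,B,rrna16s,1,Anoxybacillus kamchatkensis strain G10,99.66
MMMud_3_LB_pH8,B,reduced_rep,1,Geobacillus subterraneus PSS2,98.14
MMMud_3_LB_pH8,B,wgs,1,Geobacillus subterraneus PSS2,
MMMud_3_LB_pH8,B,rrna16s,1,Geobacillus icigianus strain G1w1,99.76
MMMud_3_LB_pH8,B,rrna16s,2,Geobacillus subterraneus PSS2 N671,99.76
MCWH_LB_pH8,C,reduced_rep,1,Brevibacillus thermoruber PM1 N690,94.13
MCWH_LB_pH8,C,wgs,1,Brevibacillus thermoruber 423,
MCWH_LB_pH8,C,rrna16s,1,Brevibacillus thermoruber PM1 N690,99.35
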