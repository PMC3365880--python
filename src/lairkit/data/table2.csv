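case,diagnosis,near_homozygous,recurrence,footnote
28,FA,No,,
29,FA,No,,
30,"FA, partially OV",No,No,
31,ATC,No,,died_lt_5mo
32,ATC,No,,died_lt_5mo
33,ATC,No,,died_lt_5mo
34,ATC,No,,died_lt_5mo
35,"ATC, partially OV",No,,died_lt_5mo
36,FTC,No,Yes,
37,"FTC, partially OV",Yes,Yes,
38,FTC-OV,Yes,,died_lt_5mo;dedifferentiated_ATC
39,FTC-OV,Yes,Yes,repeat_of_case_9
40,"FTC-OV, min. inv.",No,No,
41,"FTC-OV, min. inv.",No,No,possible_intratumour_heterogeneity
42,Mixed FTC/PTC,No,Yes,
43,PTC,No,No,
44,PTC,No,No,
45,PTC,No,No,
46,PTC,No,No,
47,PTC,No,Yes,
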