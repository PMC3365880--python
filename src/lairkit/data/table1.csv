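case,tumour_type,sex,age,dna_indices,dominant_di,chr6_state,chr6_fish,chr7_state,chr7_fish,braf,egfr,ras,pik3ca
1,FTC,m,74,1.01,1.01,AB,,AB,,-,-,NRAS,-
2,FTC,f,59,0.98,0.98,AB,,AB,,-,-,-,-
3,FTC,m,82,0.90,0.90,AB,,AB,,-,-,-,-
4,FTC/FVPC,f,65,1.02,1.02,AB,,AB,,-,-,-,-
5,FTC-OV,m,77,0.73,0.73,AAAA,2,AB,2,-,-,-,-
6,FTC-OV,m,68,0.71,0.71,A,1,AB,2,-,-,-,-
7,FTC-OV,m,59,0.67,0.67,A,1,AB,2,-,-,-,-
8,FTC-OV,m,54,1.27,1.27,AA,2,AABB,4,-,-,-,-
9,FTC-OV,m,60,1.19,1.19,AA,2,AABB,4,-,-,-,-
10,FTC-OV,m,69,1.01,1.01,A,1,AABB,4,-,-,-,-
11,FTC-OV,f,66,1.28,1.28,AA,2,AAB,3-4,-,-,-,+
12,FTC-OV,f,61,0.62/1.26,0.62,A,1,AB,4,-,-,-,-
13,FTC-OV,f,59,0.53/1.04,0.53,A,,AB,,-,-,-,-
14,FTC-OV,f,53,0.98/1.22,1.22,AA,2,AABB,4,-,-,-,-
15,FVPC,m,68,1.05,1.05,AB,,AAB,,-,-,-,-
16,PTC,m,64,1.00,1.00,AB,,AB,,+,-,-,-
17,PTC,f,65,1.02,1.02,AB,2,AB,2,+,-,-,-
18,PTC,m,62,2.06,2.06,AABB,,AABB,,+,-,-,-
19,PTC,m,72,1.02/2.05,1.02,AB,2,AB,2,+,-,-,-
20,PTC,m,62,1.07,1.07,AB,,AB,,+,-,-,-
21,PTC,f,60,0.92,0.92,AB,2,AB,2,-,-,-,-
22,PTC,f,77,0.98/2.02,0.98,AB,,AB,,-,-,NRAS,-
23,PTC,m,60,1.01,1.01,AB,,AB,,+,-,-,-
24,PTC-OV,f,72,0.94,0.94,AB,,AB,,+,-,-,-
25,PTC-OV,m,56,0.97,0.97,AB,,AB,,+,-,-,-
26,PTC-OV,f,63,1.04,1.04,AB,,AB,,+,-,-,-
27,PTC Tall Cell,m,79,1.00,1.00,AB,,AB,,+,-,-,+
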