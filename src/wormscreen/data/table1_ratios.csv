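rank,compound,blind_number,ratio,role
1,Nifedipine,15,1.69,treated
2,Masitinib,14,1.34,treated
3,WN1316,2,1.32,treated
4,BYL-719,28,1.32,treated
5,Riluzole,21,1.32,treated
6,Tubastatin A,30,1.29,treated
7,GSK-2606414,5,1.29,treated
8,Retinoic acid,16,1.29,treated
9,VORINOSTAT,29,1.29,treated
10,SA-4503,10,1.24,treated
11,CK-2017357,13,1.24,treated
12,Rasagiline,7,1.23,treated
13,Rapamycin,positive control,1.22,positive_control
14,AICAR,34,1.19,treated
15,Bromhexine,17,1.17,treated
16,-,3,1.15,treated
17,ACY-1215,31,1.14,treated
18,METFORMIN,33,1.12,treated
19,AVex-73,20,1.12,treated
20,Tamoxifen,33,1.09,treated
21,D-(+)-Trehalose,36,1.09,treated
22,Methylcobalamin,23,1.07,treated
23,SB-431542,6,1.07,treated
24,Dasatinib,11,1.06,treated
25,-,4,1.05,treated
26,Kenpaullone,1,1.03,treated
27,-,19,1.01,treated
28,Fluoxetine,38,1.00,treated
29,SPAUTIN-1,35,0.98,treated
30,Edaravone,22,0.98,treated
31,-,18,0.97,treated
32,Pyrimethamine,9,0.95,treated
33,Arimoclomol,12,0.95,treated
34,Fingolimod,37,0.94,treated
35,Deforolimus,26,0.92,treated
36,Ibudilast,8,0.91,treated
37,AZD-8055,24,0.88,treated
38,PF-04691502,27,0.84,treated
39,PP242,25,0.83,treated
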