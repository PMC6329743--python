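test,parameter,value,sd
1,PRR,0.40,0.03
1,cod_eff_anaerobic,27.2,2.5
1,release_per_cod,0.06,0.01
1,PUR,0.50,0.05
1,NUR,0.70,0.09
1,po4_eff_anoxic,12.3,1.1
1,no3_eff_anoxic,32.5,1.2
1,cod_eff_anoxic,15.5,3.1
2,PRR,4.4,0.4
2,cod_eff_anaerobic,69.4,5.5
2,release_per_cod,0.27,0.02
2,PUR,2.6,0.1
2,NUR,1.30,0.06
2,po4_eff_anoxic,41.8,1.9
2,no3_eff_anoxic,82.3,2.0
2,cod_eff_anoxic,25.8,4.2
3,PRR,0.70,0.04
3,cod_eff_anaerobic,25.5,3.1
3,release_per_cod,0.07,0.01
3,PUR,0.60,0.04
3,NUR,1.40,0.07
3,po4_eff_anoxic,15.8,1.5
3,no3_eff_anoxic,68.1,1.1
3,cod_eff_anoxic,17.5,1.8
4,PRR,4.3,0.6
4,cod_eff_anaerobic,68.1,5.1
4,release_per_cod,0.29,0.01
4,NUR,1.00,0.04
4,no3_eff_anoxic,56.0,2.2
4,cod_eff_anoxic,22.2,3.3
5,PRR,0.60,0.05
5,cod_eff_anaerobic,23.9,1.7
5,release_per_cod,0.08,0.01
5,NUR,1.10,0.09
5,no3_eff_anoxic,44.6,1.5
5,cod_eff_anoxic,15.2,2.1
6,PRR,18.3,1.1
6,cod_eff_anaerobic,85.1,3.9
6,release_per_cod,0.47,0.02
6,PUR,2.10,0.06
6,NUR,3.7,0.1
6,no3_eff_anoxic,86.4,1.7
6,cod_eff_anoxic,84.9,2.3
7,PRR,17.9,1.3
7,cod_eff_anaerobic,83.5,1.6
7,release_per_cod,0.46,0.02
7,NUR,3.0,0.1
7,no3_eff_anoxic,66.2,1.3
7,cod_eff_anoxic,79.2,5.3
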