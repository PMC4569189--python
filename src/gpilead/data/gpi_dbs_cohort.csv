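patient_id,age,sex,disease,disease_group,symptom_duration_years,hemisphere,active_location,active_config,voltage_v,pulse_width_us,frequency_hz
1,30,f,generalized dystonia,dystonia,16,left,GPi,0-3+,4.0,120,125
1,30,f,generalized dystonia,dystonia,16,right,GPi,9-10+,3.4,120,125
2,51,m,segmental dystonia,dystonia,25,left,GPi,c+ 1-,4.0,60,130
2,51,m,segmental dystonia,dystonia,25,right,IC/GPi,8-9+,3.5,60,130
3,59,f,cervical dystonia,dystonia,20,left,GPi,1-2+,3.2,120,125
3,59,f,cervical dystonia,dystonia,20,right,GPi,9-10+,3.2,120,125
4,8,m,generalized dystonia,dystonia,7,left,GPi/GPe,c+ 4-,2.0,120,130
4,8,m,generalized dystonia,dystonia,7,right,GPi,c+ 12-,2.0,120,130
5,72,f,PD,PD,14,left,GPi/GPe,2-3+,2.5,120,125
5,72,f,PD,PD,14,right,GPi,10-11+,2.5,120,125
6,72,f,PD,PD,20,left,GPi,c+ 3-,2.7,70,130
6,72,f,PD,PD,20,right,GPi,c+ 9-,2.7,70,130
7,72,m,PD,PD,8,left,GPi,c+ 3-,1.2,60,130
7,72,m,PD,PD,8,right,GPi,c+ 9-,1.6,60,130
8,69,m,PD,PD,8,left,GPi/GPe,c+ 1-,2.5,60,130
8,69,m,PD,PD,8,right,GPi,c+ 9-,2.5,60,130
9,62,m,PD,PD,6,left,GPi,c+ 3-,2.2,60,130
9,62,m,PD,PD,6,right,GPi,c+ 9-,2.2,60,130
10,62,m,segmental dystonia,dystonia,36,left,GPi/GPe,c+ 0-,4.0,90,130
10,62,m,segmental dystonia,dystonia,36,right,GPi/GPe,c+ 8-,3.0,90,130
11,76,f,segmental dystonia,dystonia,11,left,GPi,1-2+,4.0,180,125
11,76,f,segmental dystonia,dystonia,11,right,GPi,9-10+,4.0,210,125
12,73,m,PD,PD,14,left,GPi,c+ 0-,3.0,60,125
12,73,m,PD,PD,14,right,IC/GPi,c+ 8-,3.0,60,125
13,43,f,segmental dystonia,dystonia,15,left,GPi,c+ 0-,3.5,120,125
13,43,f,segmental dystonia,dystonia,15,right,GPi,c+ 8-,3.5,120,125
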