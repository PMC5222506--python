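case_id,sex,age_y,dm_type,duration_y,hba1c_pct,study_eye,bcva,dr_stage,laser,medication,dcp_density_pct,hpi,group
1,M,48,1,7,12.0,Right,20/20,NPDR,None,"Insulin, glucagon",63.46,0.432,normal_dcp
2,M,37,2,6,8.1,Right,20/15,NPDR,None,Insulin,58.02,0.429,normal_dcp
3,F,33,1,26,9.0,Right,20/20,PDR,None,Insulin,58.94,0.433,normal_dcp
4,F,33,1,25,8.0,Left,20/20,PDR,PRP,"Insulin, Metformin",55.81,0.366,dcp_nonflow
5,F,31,1,17,5.8,Right,20/20,PDR,None,Insulin,51.44,0.429,dcp_nonflow
6,F,68,2,28,10.4,Right,20/50,PDR,PRP,Insulin,46.39,0.321,dcp_nonflow
7,F,53,2,8,6.9,Right,20/25,NPDR,None,Insulin,,0.328,dcp_nonflow
8,M,43,2,6,7.4,Left,20/25,PDR,PRP,Insulin,49.52,0.314,dcp_nonflow
9,M,47,2,12,8.2,Left,20/25,PDR,None,Insulin,42.96,0.397,dcp_nonflow
10,F,33,2,5,7.2,Right,20/20,NPDR,None,Insulin,57.69,0.360,dcp_nonflow
11,M,47,2,2,7.8,Right,20/30,PDR,PRP,Metformin,47.69,0.352,dcp_nonflow
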