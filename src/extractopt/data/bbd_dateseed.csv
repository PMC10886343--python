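run,ec_pct,time_min,temp_c,tpc_rsm_pred,tpc_ann_pred,tpc_exp,tpc_sd,tfc_rsm_pred,tfc_ann_pred,tfc_exp,tfc_sd
1,80,15,50,64.99,65.59,65.15,1.15,40.71,41.66,39.25,1.05
2,80,30,40,62.3,62.6,61.56,0.52,39.28,39.25,40.25,0.98
3,60,45,60,64.13,64.89,63.55,1.15,45.29,44.57,44.8,0.56
4,60,30,50,75.7,76.88,75.26,1.01,57.41,57.95,58.32,0.28
5,60,30,50,75.77,76.85,75.56,0.89,57.41,57.2,57.01,1.15
6,60,30,50,75.87,75.32,76.15,0.69,57.41,57.69,59.4,0.89
7,80,45,50,61.57,61.6,61.95,1.0,41.65,41.25,41.53,0.79
8,60,15,60,65.62,66.29,64.55,1.15,42.98,42.77,43.83,0.69
9,60,45,40,62.97,62.57,63.35,0.69,43.52,44.09,42.67,1.09
10,40,15,50,61.21,61.55,60.92,0.59,37.5,38.83,37.62,1.1
11,60,15,40,65.8,66.33,66.39,1.01,43.28,42.62,43.77,0.99
12,40,30,60,60.34,60.95,61.09,1.15,37.14,36.99,36.17,1.09
13,40,45,50,60.38,61.75,60.23,0.79,39.1,39.56,40.56,1.0
14,60,30,50,75.17,76.6,76.65,0.49,57.41,58.25,56.32,1.02
15,60,30,50,75.77,76.05,75.25,0.89,57.41,57.85,56.01,0.58
16,40,30,40,61.1,61.59,60.89,0.92,39.41,40.66,38.79,0.65
17,80,30,60,64.03,65.6,64.15,1.09,43.03,44.25,43.64,0.45
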