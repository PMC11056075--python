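author,ref,k_total,k_rct,k_nrs,metric,bf_pooled_hn,bf_separate_hn,pp_pooled_hn,bf_pooled_hc,bf_separate_hc,pp_pooled_hc,notes
Akingboye,42,4,1,3,OR,1.541,0.649,0.606,1.626,0.615,0.619,
Aoyama,43,4,1,3,RR,4.350,0.230,0.813,4.743,0.211,0.826,
Barakakis,44,3,2,1,OR,,,,,,,no Bayesian fit computable; study counts from text
Beks,45,25,3,22,RR,2.567,0.390,0.720,3.158,0.317,0.759,
Bellos,46,3,1,2,RR,2.177,0.459,0.685,2.231,0.448,0.690,
Chan,47,7,3,4,RR,8.176,0.122,0.891,10.957,0.091,0.916,
Chiumello,48,5,4,1,RR,1.693,0.591,0.629,1.766,0.566,0.638,
Cortegiani,49,4,1,3,OR,3.301,0.303,0.768,3.574,0.280,0.781,
De Jong,50,9,3,6,OR,6.564,0.152,0.868,6.548,0.153,0.868,
Ding,51,13,2,11,OR,9.136,0.109,0.901,8.788,0.114,0.898,
Eom,52,28,23,5,OR,2.703,0.370,0.730,3.032,0.330,0.752,
Fiolet,53,7,1,6,RR,1.842,0.543,0.648,2.060,0.485,0.673,
Flannery,54,11,2,9,OR,3.437,0.291,0.775,4.096,0.244,0.804,
Hammond,55,10,6,4,RR,0.698,1.433,0.411,0.876,1.141,0.467,
Kherad,56,9,4,5,OR,2.441,0.410,0.709,2.812,0.356,0.738,
Lee,57,9,2,7,RR,2.725,0.367,0.732,3.512,0.285,0.778,
Leinicke,58,5,1,4,RR,2.357,0.424,0.702,2.628,0.381,0.724,
Liu,59,6,4,2,RR,6.936,0.144,0.874,8.830,0.113,0.898,
Luo,60,32,23,9,RR,4.229,0.236,0.809,5.700,0.175,0.851,
Mao,61,5,2,3,OR,1.142,0.875,0.533,1.336,0.749,0.572,
Mei,62,6,2,4,OR,0.543,1.842,0.352,0.709,1.411,0.415,
Poirier,63,23,8,15,OR,0.014,71.502,0.014,0.023,44.149,0.022,
Price,64,19,1,18,OR,4.781,0.209,0.827,5.385,0.186,0.843,
Ramesh,65,7,3,4,RR,4.017,0.249,0.801,4.773,0.210,0.827,
Ribeiro,66,7,2,5,RR,2.107,0.475,0.678,2.359,0.424,0.702,
Schneider,67,23,7,16,RR,0.903,1.108,0.474,1.189,0.841,0.543,
Shao,68,24,8,16,OR,0.694,1.442,0.410,0.914,1.094,0.478,
Shen,69,18,2,16,RR,9.118,0.110,0.901,11.863,0.084,0.922,
Shim,70,4,3,1,RR,4.340,0.230,0.813,4.772,0.210,0.827,
Silva,71,8,4,4,OR,7.190,0.139,0.878,9.473,0.106,0.905,
Sklar,72,8,1,7,RR,2.701,0.370,0.730,3.029,0.330,0.752,total taken as RCT+NRS (printed total ambiguous)
Stephens,73,9,2,7,OR,0.690,1.449,0.408,0.843,1.186,0.457,
Sultan,74,2,1,1,RR,1.018,0.982,0.504,1.034,0.967,0.508,
Sun,75,14,3,11,OR,3.721,0.269,0.788,4.559,0.219,0.820,
Tagaki,76,26,4,22,OR,0.183,5.473,0.154,0.243,4.115,0.195,
Tang,77,9,4,5,RR,5.104,0.196,0.836,5.981,0.167,0.857,
Teo,78,21,12,9,RR,6.388,0.157,0.865,8.782,0.114,0.898,
Tlayeh,79,13,3,10,RR,2.926,0.342,0.745,3.635,0.275,0.784,
Tsaousi,80,4,3,1,RR,5.042,0.198,0.834,5.453,0.183,0.845,
Wan,81,27,4,23,RR,2.077,0.482,0.675,2.759,0.362,0.734,
Wang,82,4,1,3,OR,1.111,0.900,0.526,1.203,0.831,0.546,
Wang,83,60,9,51,OR,0.204,4.914,0.169,0.270,3.704,0.213,
Wieczorek,84,10,2,8,OR,5.707,0.175,0.717,7.367,0.136,0.880,printed half-normal PPp inconsistent with its BF
Yang,85,9,5,4,OR,3.758,0.266,0.790,4.217,0.237,0.808,
Yao,86,6,2,4,RR,0.648,1.544,0.393,0.769,1.300,0.435,
Ye,87,5,1,4,OR,3.026,0.330,0.752,3.188,0.314,0.761,
Yedlapati,88,7,4,3,RR,0.257,3.895,0.204,0.312,3.202,0.238,
Yu,89,10,6,4,OR,2.889,0.346,0.743,3.469,0.288,0.776,
Zakhari,90,14,1,13,RR,0.524,1.908,0.344,0.323,3.098,0.244,
Zampieri,91,11,5,6,RR,7.673,0.130,0.885,10.207,0.098,0.911,
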