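method,structure,dE_eV,delta2pa_au,sigma2pa_GM,mu01_D,dmu_D,mu00_D,mu11_D
RI-CC2,"9,13-dimethyl",2.720,21307,58.0,12.188,5.100,7.837,2.796
RI-CC2,9-methyl,2.670,18170,47.4,11.684,4.818,8.102,3.663
RI-CC2,13-methyl,2.800,27544,79.1,12.148,5.922,7.044,1.207
RI-CC2,"9,10-dimethyl (Cs)",2.727,15097,41.1,12.388,4.261,8.312,4.188
RI-CC2,"9,10-dimethyl (twist)",2.680,11451,30.1,12.102,3.752,7.991,4.424
RI-CC2,"9,10,13-trimethyl (Cs)",2.600,31434,78.0,12.238,5.865,8.527,2.677
RI-CC2,"9,10,13-trimethyl (twist)",2.510,16752,38.5,11.337,4.506,7.625,3.258
M11,"9,13-dimethyl",2.914,4713,14.8,11.253,2.899,6.942,4.053
M11,9-methyl,2.851,3494,10.5,10.836,2.576,7.081,4.641
M11,13-methyl,3.005,6378,21.2,11.263,3.407,6.336,2.939
M11,"9,10-dimethyl (Cs)",2.888,3055,9.4,11.398,2.344,7.357,5.070
M11,"9,10-dimethyl (twist)",2.830,2156,6.4,11.077,2.030,6.991,5.045
M11,"9,10,13-trimethyl (Cs)",2.805,7959,23.0,11.301,3.583,7.804,4.231
M11,"9,10,13-trimethyl (twist)",2.689,4432,11.8,10.287,2.860,7.008,4.192
MN15,"9,13-dimethyl",2.918,1655,5.2,11.035,1.739,6.497,4.771
MN15,9-methyl,2.861,1136,3.4,10.560,1.492,6.690,5.289
MN15,13-methyl,2.988,2504,8.2,11.068,2.133,5.771,3.651
MN15,"9,10-dimethyl (Cs)",2.916,920,2.9,11.160,1.327,6.993,5.728
MN15,"9,10-dimethyl (twist)",2.861,573,1.7,10.835,1.088,6.663,5.639
MN15,"9,10,13-trimethyl (Cs)",2.790,2986,8.6,10.974,2.224,7.259,5.034
MN15,"9,10,13-trimethyl (twist)",2.683,1423,3.8,10.065,1.642,6.483,4.899
CAM-B3LYP,"9,13-dimethyl",2.950,2187,7.0,11.179,2.007,6.533,4.537
CAM-B3LYP,9-methyl,2.880,1541,4.7,10.710,1.749,6.704,4.975
CAM-B3LYP,13-methyl,3.020,3267,10.9,11.212,2.449,5.857,3.417
CAM-B3LYP,"9,10-dimethyl (Cs)",2.930,1266,4.0,11.307,1.549,7.000,5.451
CAM-B3LYP,"9,10-dimethyl (twist)",2.880,810,2.5,10.979,1.285,6.652,5.370
CAM-B3LYP,"9,10,13-trimethyl (Cs)",2.830,3987,11.7,11.173,2.580,7.332,4.753
CAM-B3LYP,"9,10,13-trimethyl (twist)",2.720,2037,5.5,10.222,1.977,6.567,4.599
BHandHLYP,"9,13-dimethyl",3.020,1660,5.5,11.263,1.849,6.334,4.495
BHandHLYP,9-methyl,2.960,1143,3.7,10.785,1.612,6.500,4.908
BHandHLYP,13-methyl,3.100,2597,9.2,11.313,2.284,5.606,3.331
BHandHLYP,"9,10-dimethyl (Cs)",3.010,939,3.1,11.384,1.430,6.812,5.383
BHandHLYP,"9,10-dimethyl (twist)",2.960,547,1.8,11.063,1.147,6.460,5.315
BHandHLYP,"9,10,13-trimethyl (Cs)",2.910,3239,10.1,11.283,2.435,7.115,4.680
BHandHLYP,"9,10,13-trimethyl (twist)",2.800,1595,4.6,10.315,1.848,6.360,4.524
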