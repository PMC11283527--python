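id,model,feature_map,ACC,SV,SP,PR,ER,FPR,FNR,NPV,F1S
A1,A.CSVM,gwo1,0.945,0.883,0.961,0.892,0.054,0.038,0.116,0.962,0.887
A2,A.WNN,gwo1,0.945,0.899,0.961,0.908,0.054,0.039,0.100,0.961,0.903
A3,A.QSVM,gwo1,0.942,0.877,0.958,0.897,0.057,0.041,0.122,0.959,0.885
A4,A.MNN,gwo1,0.941,0.892,0.958,0.894,0.058,0.041,0.107,0.958,0.893
A5,A.CSVM,gwo2,0.943,0.880,0.959,0.900,0.056,0.040,0.119,0.960,0.888
A6,A.WNN,gwo2,0.941,0.887,0.958,0.898,0.058,0.042,0.112,0.958,0.892
A7,A.QSVM,gwo2,0.938,0.872,0.956,0.890,0.061,0.044,0.127,0.956,0.879
A8,A.MNN,gwo2,0.939,0.878,0.956,0.897,0.060,0.043,0.122,0.957,0.887
A9,A.CSVM,original,0.945,0.883,0.960,0.903,0.054,0.039,0.116,0.961,0.892
A10,A.WNN,original,0.943,0.892,0.959,0.900,0.057,0.040,0.108,0.959,0.895
A11,A.QSVM,original,0.940,0.875,0.957,0.893,0.059,0.042,0.124,0.958,0.883
A12,A.MNN,original,0.940,0.885,0.957,0.895,0.059,0.042,0.114,0.957,0.890
A13,I.CSVM,gwo1,0.925,0.826,0.947,0.855,0.074,0.052,0.173,0.949,0.837
A14,I.WNN,gwo1,0.921,0.834,0.945,0.841,0.078,0.055,0.165,0.945,0.837
A15,I.QSVM,gwo1,0.920,0.821,0.943,0.840,0.079,0.056,0.178,0.944,0.829
A16,I.MNN,gwo1,0.920,0.838,0.944,0.832,0.079,0.055,0.161,0.944,0.835
A17,I.CSVM,gwo2,0.915,0.809,0.940,0.836,0.084,0.060,0.190,0.941,0.820
A18,I.WNN,gwo2,0.916,0.826,0.941,0.825,0.083,0.058,0.173,0.941,0.826
A19,I.QSVM,gwo2,0.913,0.806,0.938,0.835,0.086,0.061,0.193,0.939,0.817
A20,I.MNN,gwo2,0.884,0.703,0.914,0.702,0.115,0.085,0.296,0.914,0.702
A21,I.CSVM,original,0.929,0.840,0.950,0.862,0.070,0.049,0.159,0.951,0.850
A22,I.WNN,original,0.928,0.846,0.950,0.852,0.071,0.050,0.153,0.950,0.849
A23,I.QSVM,original,0.929,0.846,0.950,0.861,0.070,0.049,0.153,0.951,0.852
A24,I.MNN,original,0.925,0.841,0.948,0.847,0.074,0.052,0.158,0.948,0.844
A25,M.CSVM,gwo1,0.885,0.764,0.917,0.804,0.115,0.082,0.235,0.919,0.782
A26,M.WNN,gwo1,0.886,0.776,0.919,0.781,0.114,0.080,0.223,0.919,0.778
A27,M.QSVM,gwo1,0.883,0.764,0.916,0.795,0.116,0.083,0.235,0.917,0.778
A28,M.LSVM,gwo1,0.886,0.765,0.918,0.802,0.114,0.081,0.235,0.919,0.781
A29,M.SD,gwo1,0.861,0.727,0.902,0.733,0.138,0.097,0.272,0.902,0.730
A30,M.CSVM,gwo2,0.869,0.730,0.907,0.765,0.130,0.093,0.269,0.908,0.745
A31,M.WNN,gwo2,0.864,0.735,0.904,0.740,0.136,0.095,0.264,0.904,0.737
A32,M.QSVM,gwo2,0.869,0.732,0.907,0.762,0.130,0.092,0.267,0.908,0.745
A33,M.LSVM,gwo2,0.874,0.732,0.910,0.787,0.125,0.090,0.267,0.911,0.755
A34,M.SD,gwo2,0.869,0.748,0.907,0.760,0.130,0.092,0.251,0.908,0.754
A35,M.CSVM,original,0.882,0.760,0.915,0.799,0.117,0.084,0.239,0.917,0.777
A36,M.WNN,original,0.882,0.774,0.916,0.779,0.117,0.083,0.225,0.916,0.776
A37,M.QSVM,original,0.882,0.762,0.916,0.795,0.117,0.084,0.237,0.916,0.777
A38,M.LSVM,original,0.885,0.759,0.918,0.801,0.114,0.081,0.240,0.919,0.777
A39,M.SD,original,0.834,0.686,0.883,0.672,0.165,0.116,0.313,0.883,0.678
A40,R.CSVM,gwo1,0.929,0.844,0.949,0.864,0.070,0.050,0.155,0.951,0.851
A41,R.WNN,gwo1,0.931,0.850,0.950,0.870,0.068,0.049,0.149,0.952,0.858
A42,R.QSVM,gwo1,0.932,0.863,0.952,0.858,0.067,0.047,0.136,0.952,0.861
A43,R.MNN,gwo1,0.943,0.874,0.960,0.881,0.056,0.039,0.125,0.960,0.875
A44,R.CSVM,gwo2,0.928,0.850,0.949,0.862,0.071,0.050,0.150,0.950,0.854
A45,R.WNN,gwo2,0.924,0.835,0.945,0.856,0.075,0.054,0.164,0.947,0.842
A46,R.QSVM,gwo2,0.927,0.846,0.948,0.859,0.072,0.051,0.154,0.949,0.850
A47,R.MNN,gwo2,0.926,0.847,0.948,0.851,0.073,0.051,0.152,0.948,0.849
A48,R.CSVM,original,0.932,0.854,0.951,0.869,0.067,0.048,0.145,0.952,0.859
A49,R.WNN,original,0.932,0.852,0.951,0.869,0.067,0.048,0.147,0.952,0.858
A50,R.QSVM,original,0.932,0.856,0.951,0.872,0.067,0.048,0.143,0.952,0.862
A51,R.MNN,original,0.9308,0.8578,0.9513,0.8568,0.0692,0.0487,0.1422,0.9514,0.8570
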