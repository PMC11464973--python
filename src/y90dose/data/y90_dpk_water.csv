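radius_mm,dose_gy_per_decay
0.025,5.25532e-06
0.075,3.96818e-07
0.125,2.02164e-07
0.175,7.4309e-08
0.225,6.10437e-08
0.275,3.08837e-08
0.325,2.85353e-08
0.375,1.7073e-08
0.425,1.62957e-08
0.475,1.0912e-08
0.525,1.04184e-08
0.575,7.62192e-09
0.625,7.18009e-09
0.675,5.63231e-09
0.725,5.22521e-09
0.775,4.33127e-09
0.825,3.96414e-09
0.875,3.41905e-09
0.925,3.10115e-09
0.975,2.75526e-09
1.025,2.4934e-09
1.075,2.25282e-09
1.125,2.04698e-09
1.175,1.88115e-09
1.225,1.70876e-09
1.275,1.58254e-09
1.325,1.45021e-09
1.375,1.34902e-09
1.425,1.23946e-09
1.475,1.16021e-09
1.525,1.0723e-09
1.575,1.0065e-09
1.625,9.37139e-10
1.675,8.7951e-10
1.725,8.21483e-10
1.775,7.7352e-10
1.825,7.26548e-10
1.875,6.84786e-10
1.925,6.44151e-10
1.975,6.07578e-10
2.025,5.75176e-10
2.075,5.44509e-10
2.125,5.16115e-10
2.175,4.88884e-10
2.225,4.63701e-10
2.275,4.39517e-10
2.325,4.18832e-10
2.375,3.9834e-10
2.425,3.79156e-10
2.475,3.61248e-10
2.525,3.4492e-10
2.575,3.27659e-10
2.625,3.13533e-10
2.675,2.99251e-10
2.725,2.85812e-10
2.775,2.73226e-10
2.825,2.61193e-10
2.875,2.49389e-10
2.925,2.38746e-10
2.975,2.28842e-10
3.025,2.18909e-10
3.075,2.09415e-10
3.125,2.01131e-10
3.175,1.92579e-10
3.225,1.84282e-10
3.275,1.7725e-10
3.325,1.70104e-10
3.375,1.62679e-10
3.425,1.56147e-10
3.475,1.49887e-10
3.525,1.43929e-10
3.575,1.38194e-10
3.625,1.32679e-10
3.675,1.27448e-10
3.725,1.22347e-10
3.775,1.17842e-10
3.825,1.1316e-10
3.875,1.08373e-10
3.925,1.04163e-10
3.975,1.00332e-10
4.025,9.65669e-11
4.075,9.28953e-11
4.125,8.92422e-11
4.175,8.56038e-11
4.225,8.24369e-11
4.275,7.8998e-11
4.325,7.59133e-11
4.375,7.31791e-11
4.425,7.0251e-11
4.475,6.76936e-11
4.525,6.50154e-11
4.575,6.24461e-11
4.625,5.99477e-11
4.675,5.75884e-11
4.725,5.54259e-11
4.775,5.31018e-11
4.825,5.09225e-11
4.875,4.89461e-11
4.925,4.67991e-11
4.975,4.48012e-11
5.025,4.291e-11
5.075,4.13376e-11
5.125,3.96613e-11
5.175,3.80709e-11
5.225,3.65168e-11
5.275,3.47057e-11
5.325,3.32925e-11
5.375,3.18388e-11
5.425,3.04909e-11
5.475,2.93126e-11
5.525,2.80379e-11
5.575,2.66606e-11
5.625,2.54699e-11
5.675,2.4441e-11
5.725,2.33549e-11
5.775,2.22944e-11
5.825,2.1297e-11
5.875,2.02848e-11
5.925,1.93134e-11
5.975,1.84504e-11
6.025,1.76222e-11
6.075,1.67332e-11
6.125,1.60022e-11
6.175,1.50855e-11
6.225,1.43906e-11
6.275,1.3627e-11
6.325,1.28457e-11
6.375,1.2239e-11
6.425,1.15846e-11
6.475,1.10094e-11
6.525,1.03823e-11
6.575,9.89498e-12
6.625,9.34893e-12
6.675,8.87265e-12
6.725,8.30649e-12
6.775,7.83168e-12
6.825,7.38343e-12
6.875,6.93318e-12
6.925,6.52815e-12
6.975,6.13199e-12
7.025,5.73051e-12
7.075,5.41178e-12
7.125,5.01733e-12
7.175,4.75948e-12
7.225,4.43154e-12
7.275,4.13686e-12
7.325,3.8443e-12
7.375,3.56447e-12
7.425,3.34338e-12
7.475,3.1241e-12
7.525,2.89062e-12
7.575,2.7066e-12
7.625,2.48668e-12
7.675,2.28775e-12
7.725,2.08202e-12
7.775,1.91694e-12
7.825,1.78761e-12
7.875,1.64168e-12
7.925,1.49891e-12
7.975,1.37222e-12
8.025,1.28037e-12
8.075,1.17201e-12
8.125,1.06168e-12
8.175,9.72843e-13
8.225,8.86316e-13
8.275,8.00647e-13
8.325,7.17545e-13
8.375,6.68176e-13
8.425,6.17638e-13
8.475,5.4282e-13
8.525,4.81199e-13
8.575,4.19327e-13
8.625,3.85747e-13
8.675,3.27441e-13
8.725,2.94407e-13
8.775,2.52327e-13
8.825,2.25203e-13
8.875,1.95732e-13
8.925,1.62529e-13
8.975,1.43264e-13
9.025,1.22428e-13
9.075,1.0905e-13
9.125,9.2614e-14
9.175,7.86873e-14
9.225,6.20276e-14
9.275,5.39541e-14
9.325,4.41667e-14
9.375,3.47386e-14
9.425,2.77826e-14
9.475,2.3834e-14
9.525,1.94607e-14
9.575,1.37533e-14
9.625,1.14733e-14
9.675,8.67536e-15
9.725,7.42866e-15
9.775,4.35683e-15
9.825,3.33356e-15
9.875,3.04034e-15
9.925,2.05007e-15
9.975,1.83446e-15
10.025,1.23977e-15
10.075,3.12953e-16
10.125,2.31619e-16
10.175,3.76001e-16
10.225,3.79073e-16
10.275,1.95354e-16
10.325,2.03378e-16
10.375,1.62244e-16
10.425,1.01136e-16
10.475,0
10.525,0
10.575,0
10.625,0
10.675,0
10.725,0
10.775,0
10.825,0
10.875,0
10.925,0
10.975,0
11.025,0
11.075,0
11.125,0
11.175,0
11.225,0
11.275,0
11.325,0
11.375,0
11.425,0
11.475,0
11.525,0
11.575,0
11.625,0
11.675,0
11.725,0
11.775,0
11.825,0
11.875,0
11.925,0
11.975,0
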