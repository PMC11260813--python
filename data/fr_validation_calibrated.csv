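station,year,scale,model,r2,rmse,mae,wi
Baoding,2015,daily,fr_calibrated,0.652,1.334,0.968,0.894
Baoding,2015,dekad,fr_calibrated,0.877,0.904,0.717,0.936
Baoding,2015,monthly,fr_calibrated,0.782,0.806,0.598,0.939
Baoding,2016,daily,fr_calibrated,0.609,1.305,0.939,0.877
Baoding,2016,dekad,fr_calibrated,0.849,0.939,0.759,0.916
Baoding,2016,monthly,fr_calibrated,0.725,0.898,0.748,0.918
Baoding,2017,daily,fr_calibrated,0.67,1.361,0.99,0.894
Baoding,2017,dekad,fr_calibrated,0.812,0.887,0.7,0.94
Baoding,2017,monthly,fr_calibrated,0.859,0.733,0.662,0.955
Baoding,2018,daily,fr_calibrated,0.63,1.451,1.06,0.887
Baoding,2018,dekad,fr_calibrated,0.727,1.017,0.799,0.921
Baoding,2018,monthly,fr_calibrated,0.778,0.888,0.67,0.929
Baoding,2019,daily,fr_calibrated,0.6,1.6,1.2,0.872
Baoding,2019,dekad,fr_calibrated,0.673,1.282,0.924,0.896
Baoding,2019,monthly,fr_calibrated,0.701,1.197,0.901,0.905
Xinji,2017,daily,fr_calibrated,0.805,1.106,0.816,0.944
Xinji,2017,dekad,fr_calibrated,0.894,0.746,0.57,0.967
Xinji,2017,monthly,fr_calibrated,0.926,0.632,0.512,0.973
Xinji,2018,daily,fr_calibrated,0.743,1.251,0.9,0.923
Xinji,2018,dekad,fr_calibrated,0.849,0.856,0.637,0.95
Xinji,2018,monthly,fr_calibrated,0.88,0.762,0.499,0.954
Xinji,2019,daily,fr_calibrated,0.771,1.121,0.833,0.936
Xinji,2019,dekad,fr_calibrated,0.852,0.783,0.6,0.96
Xinji,2019,monthly,fr_calibrated,0.876,0.686,0.506,0.966
Xinji,2020,daily,fr_calibrated,0.754,1.117,0.934,0.918
Xinji,2020,dekad,fr_calibrated,0.856,1.042,0.736,0.939
Xinji,2020,monthly,fr_calibrated,0.903,0.934,0.674,0.945
Xinji,2021,daily,fr_calibrated,0.656,1.26,0.965,0.882
Xinji,2021,dekad,fr_calibrated,0.741,0.939,0.707,0.915
Xinji,2021,monthly,fr_calibrated,0.768,0.871,0.687,0.928
Handan,2015,daily,fr_calibrated,0.675,1.728,1.218,0.822
Handan,2015,dekad,fr_calibrated,0.81,1.324,0.904,0.862
Handan,2015,monthly,fr_calibrated,0.909,0.939,0.656,0.914
Handan,2016,daily,fr_calibrated,0.693,1.288,1.036,0.876
Handan,2016,dekad,fr_calibrated,0.848,0.81,0.689,0.93
Handan,2016,monthly,fr_calibrated,0.885,0.691,0.629,0.943
Handan,2017,daily,fr_calibrated,0.751,1.365,1.014,0.886
Handan,2017,dekad,fr_calibrated,0.907,0.854,0.668,0.941
Handan,2017,monthly,fr_calibrated,0.943,0.667,0.547,0.958
Handan,2018,daily,fr_calibrated,0.664,1.462,1.019,0.857
Handan,2018,dekad,fr_calibrated,0.838,0.856,0.605,0.925
Handan,2018,monthly,fr_calibrated,0.89,0.68,0.415,0.947
Handan,2019,daily,fr_calibrated,0.681,1.884,1.244,0.801
Handan,2019,dekad,fr_calibrated,0.856,1.416,0.967,0.853
Handan,2019,monthly,fr_calibrated,0.896,1.296,0.811,0.866
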