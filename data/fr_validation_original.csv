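station,year,scale,model,r2,rmse,mae,wi
Baoding,2015,daily,fr,0.652,1.625,1.103,0.801
Baoding,2015,dekad,fr,0.877,1.321,1.006,0.862
Baoding,2015,monthly,fr,0.782,1.219,0.973,0.825
Baoding,2016,daily,fr,0.609,1.58,1.097,0.781
Baoding,2016,dekad,fr,0.849,1.363,0.991,0.823
Baoding,2016,monthly,fr,0.725,1.321,0.956,0.788
Baoding,2017,daily,fr,0.67,1.774,1.191,0.778
Baoding,2017,dekad,fr,0.812,1.465,1.085,0.837
Baoding,2017,monthly,fr,0.859,1.374,1.065,0.809
Baoding,2018,daily,fr,0.63,1.575,1.06,0.824
Baoding,2018,dekad,fr,0.727,1.211,0.965,0.888
Baoding,2018,monthly,fr,0.778,1.097,0.908,0.856
Baoding,2019,daily,fr,0.6,1.6,1.2,0.822
Baoding,2019,dekad,fr,0.673,1.337,1.065,0.887
Baoding,2019,monthly,fr,0.701,1.247,0.972,0.859
Xinji,2017,daily,fr,0.805,1.25,0.906,0.906
Xinji,2017,dekad,fr,0.894,0.963,0.789,0.945
Xinji,2017,monthly,fr,0.926,0.856,0.706,0.934
Xinji,2018,daily,fr,0.743,1.267,0.91,0.894
Xinji,2018,dekad,fr,0.849,0.894,0.685,0.945
Xinji,2018,monthly,fr,0.88,0.798,0.67,0.934
Xinji,2019,daily,fr,0.771,1.323,0.881,0.886
Xinji,2019,dekad,fr,0.852,1.055,0.717,0.927
Xinji,2019,monthly,fr,0.876,0.979,0.675,0.912
Xinji,2020,daily,fr,0.754,1.179,1.145,0.91
Xinji,2020,dekad,fr,0.856,1.05,0.7,0.957
Xinji,2020,monthly,fr,0.903,1.023,0.658,0.96
Xinji,2021,daily,fr,0.656,1.26,1.12,0.861
Xinji,2021,dekad,fr,0.741,0.925,0.76,0.917
Xinji,2021,monthly,fr,0.768,0.896,0.773,0.898
Handan,2015,daily,fr,0.675,2.043,1.699,0.842
Handan,2015,dekad,fr,0.81,1.677,1.49,0.778
Handan,2015,monthly,fr,0.909,1.465,1.345,0.874
Handan,2016,daily,fr,0.693,2.327,1.989,0.782
Handan,2016,dekad,fr,0.848,2.062,1.895,0.548
Handan,2016,monthly,fr,0.885,1.999,1.884,0.765
Handan,2017,daily,fr,0.751,2.172,1.845,0.834
Handan,2017,dekad,fr,0.907,1.869,1.741,0.715
Handan,2017,monthly,fr,0.943,1.807,1.727,0.832
Handan,2018,daily,fr,0.664,2.252,1.923,0.804
Handan,2018,dekad,fr,0.838,1.886,1.688,0.637
Handan,2018,monthly,fr,0.89,1.814,1.685,0.8
Handan,2019,daily,fr,0.681,1.985,1.66,0.853
Handan,2019,dekad,fr,0.856,1.492,1.345,0.837
Handan,2019,monthly,fr,0.896,1.408,1.29,0.897
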