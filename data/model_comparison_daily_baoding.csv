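station,year_type,scale,model,r2,rmse,mae,wi
Baoding,high_flow,daily,pt,0.637,1.886,1.554,0.67
Baoding,high_flow,daily,ha,0.6,5.222,4.226,0.485
Baoding,high_flow,daily,mc,0.359,2.115,1.714,0.731
Baoding,high_flow,daily,fr,0.685,1.227,0.891,0.853
Baoding,median_water,daily,pt,0.755,2.483,1.839,0.68
Baoding,median_water,daily,ha,0.747,4.965,4.05,0.661
Baoding,median_water,daily,mc,0.566,2.056,1.649,0.856
Baoding,median_water,daily,fr,0.799,1.626,1.103,0.867
Baoding,low_flow,daily,pt,0.695,2.161,1.606,0.698
Baoding,low_flow,daily,ha,0.715,5.249,4.293,0.598
Baoding,low_flow,daily,mc,0.486,2.105,1.577,0.819
Baoding,low_flow,daily,fr,0.724,1.441,0.99,0.867
Baoding,special_dry,daily,pt,0.754,2.721,2.052,0.669
Baoding,special_dry,daily,ha,0.751,4.978,4.036,0.675
Baoding,special_dry,daily,mc,0.591,2.231,1.736,0.859
Baoding,special_dry,daily,fr,0.784,1.876,1.277,0.837
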