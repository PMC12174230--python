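case,body_weight_kg,octtotal,dose_per_bw_MBq_per_kg,measured_late_edr_uSv_per_h,predicted_late_edr_uSv_per_h,printed_abs_error_uSv_per_h
1,37.4,6186,193,7.0,13.1,6.1
2,86.4,7932,83,4.5,5.3,0.8
3,66.0,9632,110,5.5,8.2,2.7
4,57.4,4486,127,5.4,7.0,1.6
5,80.5,11530,89,8.4,7.6,0.8
6,52.9,4164,136,6.0,7.7,1.7
7,40.5,4091,177,5.2,10.9,5.8
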