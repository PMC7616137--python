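patient_id,age,sex,n_events,first_match_date,mean_value,on_med
p1,42,F,1,2020-01-01,10.0,true
p2,22,M,1,2020-01-01,,false
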