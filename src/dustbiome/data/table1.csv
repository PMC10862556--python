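sample_id,start_date,end_date,pm10,pm25,pm10_pm25_ratio,saharan_dust,dust_label,la_ce,la_v
S1,2018-08-10,2018-08-11,44.7,12.2,3.7,3.2,low,0.67,0.28
S2,2018-08-11,2018-08-12,58.1,19.8,2.9,24.8,medium,0.54,0.25
S3,2018-08-12,2018-08-13,115.7,37.9,3.1,65.7,peak,0.52,0.29
S4,2018-08-13,2018-08-14,104.7,30.7,3.4,54.3,peak,0.51,0.28
S5,2018-08-14,2018-08-15,84.4,22.2,3.8,42.5,peak,0.54,0.26
S6,2018-08-15,2018-08-16,64.6,13.7,4.7,12.0,medium,0.52,0.22
S7,2018-08-16,2018-08-17,74.4,13.9,5.4,2.0,low,0.52,0.20
S8,2018-08-17,2018-08-18,55.2,11.3,4.9,14.0,medium,0.58,0.22
S9,2018-08-18,2018-08-19,45.1,9.3,4.8,2.1,low,0.55,0.14
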