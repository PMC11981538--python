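variable,unit,pre_year,pre_value,post_year,post_value,printed_percent_change
Mean water depth,m,1971,1.10,2011,1.20,9.09
Mean annual water temperature,degC,1971,15.33,2009,19.28,25.77
Mean summer water temperature,degC,1971,24.16,2009,25.69,6.33
Mean annual water salinity,ppt,1971,35.19,2009,36.10,2.59
Mean summer water salinity,ppt,1971,35.92,2009,37.00,3.01
Mean annual Chlorophyll-a,ug/L,1978,<1.00,2009,54.00,5300.0
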