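case_id,sex,age_years,tumour_volume_cm3,mri_interval_months,growth_rate_pct_per_year,classification
VS01,F,27,0.10,6,-40.00,static
VS02,M,39,1.66,12,15.79,static
VS03,M,64,12.4,2,5.91,static
VS04,M,34,3.54,4,-9.04,static
VS05,F,43,3.47,10,33.98,growing
VS06,M,45,2.52,0,170.45,growing
VS07,M,68,1.70,5,222.08,growing
VS08,M,34,12.1,8,28.02,growing
VS09,M,62,0.19,2,266.67,growing
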