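woman_id,maternity_id,delivery_date,gestation_weeks
W1,M1,2004-06-30,40
W2,M2,2005-03-15,38
W3,M3,2003-05-10,41
W4,M4,2006-01-20,37
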