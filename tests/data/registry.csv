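woman_id,registry_id,diagnosis_date,group,first_notification_date
W1,R1,2004-08-10,breast,2004-08-10
W2,R2,2005-01-05,melanoma,2005-01-05
W3,R3,2003-09-01,colorectal,2003-09-01
W4,R4,1999-04-01,lymphohaematopoeitic,1999-04-01
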