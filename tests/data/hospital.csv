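woman_id,record_id,admission_date,diag1,diag2,diag3,diag4,diag5
W1,H1,2004-08-01,O26.8,C50.9,,,
W2,H2,2004-12-28,C43.5,,,,
W4,H3,2006-03-05,C91.0,,,,
W1,H4,2004-09-15,C50.4,,,,
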