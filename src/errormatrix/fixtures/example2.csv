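study_id,level,outcome,grade_score,adverse,a,b,c,d,estimate,ci_lower,ci_upper,se,direction,code
Byrne-Quinn,1d,all-cause mortality,9,true,,,,,,,,2.02,harm,
Hillestad,1d,all-cause mortality,9,true,,,,,,,,2.00,harm,
Karlson,1d,all-cause mortality,9,true,,,,,,,,1.42,harm,
Lloyd,1d,all-cause mortality,9,true,,,,,,,,1.55,harm,
PAFAC,1b,all-cause mortality,9,true,,,,,,,,0.78,harm,
Sodermark,1d,all-cause mortality,9,true,,,,,,,,0.73,harm,
SOPAT,1b,all-cause mortality,9,true,,,,,,,,1.51,harm,
Steinbeck,1d,all-cause mortality,9,true,,,,,,,,,,Z
Lafuente-Lafuente,1c,all-cause mortality,9,true,,,,,2.39,1.03,5.59,,,
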