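study_id,level,outcome,grade_score,adverse,a,b,c,d,estimate,ci_lower,ci_upper,se,direction,code
Bangalore,1a,all-cause mortality,9,true,,,,,,,,0.12,harm,
Bangalore,1a,cardiovascular mortality,8,true,,,,,,,,0.16,harm,
Bangalore,1a,non-fatal myocardial infarction,7,true,,,,,,,,0.10,benefit,
Bangalore,1a,non-fatal stroke,7,true,,,,,,,,0.28,harm,
Poise,1b,all-cause mortality,9,true,,,,,,,,0.13,harm,
Poise,1b,cardiovascular mortality,8,true,,,,,,,,0.17,harm,
Poise,1b,non-fatal myocardial infarction,7,true,,,,,,,,0.10,benefit,
Poise,1b,non-fatal stroke,7,true,,,,,,,,0.33,harm,
MaVS,1b,all-cause mortality,9,true,,,,,,,,1.07,harm,
MaVS,1b,cardiovascular mortality,8,true,,,,,,,,,,Z
MaVS,1b,non-fatal myocardial infarction,7,true,,,,,,,,,,N
MaVS,1b,non-fatal stroke,7,true,,,,,,,,0.66,harm,
Dipom,1b,all-cause mortality,9,true,,,,,,,,0.34,harm,
Dipom,1b,cardiovascular mortality,8,true,,,,,,,,0.48,harm,
Dipom,1b,non-fatal myocardial infarction,7,true,,,,,,,,0.91,benefit,
Dipom,1b,non-fatal stroke,7,true,,,,,,,,,,Z
Mangano,1b,all-cause mortality,9,true,,,,,,,,0.85,harm,
Mangano,1b,cardiovascular mortality,8,true,,,,,,,,1.22,harm,
Mangano,1b,non-fatal myocardial infarction,7,true,,,,,,,,1.22,benefit,
Mangano,1b,non-fatal stroke,7,true,,,,,,,,1.11,harm,
Bangalore,1c,all-cause mortality,9,true,,,,,,,,0.11,harm,
Bangalore,1c,cardiovascular mortality,8,true,,,,,,,,0.15,harm,
Bangalore,1c,non-fatal myocardial infarction,7,true,,,,,,,,0.09,benefit,
Bangalore,1c,non-fatal stroke,7,true,,,,,,,,0.28,harm,
Wetterslev,1c,all-cause mortality,9,true,,,,,,,,0.24,harm,
Wetterslev,1c,cardiovascular mortality,8,true,,,,,,,,,,N
Wetterslev,1c,non-fatal myocardial infarction,7,true,,,,,,,,0.23,benefit,
Wetterslev,1c,non-fatal stroke,7,true,,,,,,,,,,N
Poldermans,1d,all-cause mortality,9,true,,,,,,,,0.76,harm,
Poldermans,1d,cardiovascular mortality,8,true,,,,,,,,0.76,harm,
Poldermans,1d,non-fatal myocardial infarction,7,true,,,,,,,,,,Z
Poldermans,1d,non-fatal stroke,7,true,,,,,,,,,,N
Lindenauer,2b,all-cause mortality,9,true,,,,,,,,0.02,harm,
Lindenauer,2b,cardiovascular mortality,8,true,,,,,,,,,,N
Lindenauer,2b,non-fatal myocardial infarction,7,true,,,,,,,,,,N
Lindenauer,2b,non-fatal stroke,7,true,,,,,,,,,,N
AHA Guidelines,5,all-cause mortality,9,true,,,,,,,,,,N
AHA Guidelines,5,cardiovascular mortality,8,true,,,,,,,,,,N
AHA Guidelines,5,non-fatal myocardial infarction,7,true,,,,,,,,,,N
AHA Guidelines,5,non-fatal stroke,7,true,,,,,,,,,,N
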