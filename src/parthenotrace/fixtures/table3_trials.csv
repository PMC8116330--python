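female_id,inseminate,group,eggs_laid,n_eggs,n_fertile_ai,n_parthenote,n_hatched_ai,first_fertile_day,last_fertile_day,duration_printed,fertility_pct_printed,hatchability_pct_printed,fertility_printed_is_raw,parthenote_days,parthenote_ids
854,320-E1,fresh,43,41,11,1,9,14,121,107,26.8,22.0,false,4,AI-P1
101,381-E2,fresh,30,30,17,0,15,8,111,103,56.7,50.0,false,,
283,381-E4,fresh,32,30,20,0,18,15,116,101,66.7,60.0,false,,
268,381-E5,fresh,36,36,21,0,14,6,103,97,58.3,38.9,false,,
793,395-E1,cold24,27,23,12,0,12,10,79,69,52.2,52.2,false,,
036,320-E3,fresh,34,32,12,0,11,12,63,51,37.5,34.4,false,,
581,381-E1,fresh,32,31,4,0,3,8,63,55,12.9,9.7,false,,
512,381-E3,fresh,12,11,3,0,3,11,60,49,27.3,27.3,false,,
034,381-E3,fresh,19,19,5,0,5,16,60,44,26.3,26.3,false,,
370,2969-E1,cold24,18,18,2,0,2,19,49,30,11.1,11.1,false,,
785,381-E4,fresh,26,24,1,0,1,10,10,1,4.2,4.2,false,,
376,381-E1,cold48,14,14,1,0,1,44,44,1,7.1,7.1,false,,
307,320-E1,fresh,39,39,1,2,1,13,13,1,7.7,2.6,true,87;91,AI-P2;AI-P3
626,395-E1,cold24,19,5,1,0,1,59,59,1,20.0,20.0,false,,
583,395-E1,cold24,22,11,1,0,1,60,60,1,9.1,9.1,false,,
063,381-E2,fresh,16,16,0,0,0,,,,0.0,0.0,false,,
775,381-E3,fresh,16,16,0,0,0,,,,0.0,0.0,false,,
551,381-E5,fresh,6,6,0,0,0,,,,0.0,0.0,false,,
065,320-E2,fresh,26,26,0,0,0,,,,0.0,0.0,false,,
095,320-E2,fresh,2,2,0,0,0,,,,0.0,0.0,false,,
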