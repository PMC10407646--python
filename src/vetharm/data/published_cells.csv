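stratum,exposure_group,selfharm_yes,selfharm_no
LOW,NEITHER,6792,3065664
LOW,TBI_ONLY,215,25409
LOW,PTSD_ONLY,3407,209468
LOW,COMORBID,330,16330
MEDIUM,NEITHER,9466,1377527
MEDIUM,TBI_ONLY,558,22851
MEDIUM,PTSD_ONLY,7548,234050
MEDIUM,COMORBID,1342,26252
HIGH,NEITHER,21979,1123012
HIGH,TBI_ONLY,2335,42498
HIGH,PTSD_ONLY,25894,412053
HIGH,COMORBID,6778,51517
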