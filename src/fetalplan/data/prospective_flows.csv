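case_id,efw_kg,vessel,method,flow_mL_min,indexed_printed,delta_printed
3,3.47,DAo,automated,670,193,
4,2.38,DAo,automated,400,168,14.9
4,2.38,DAo,automated,457,192,2.8
4,2.38,DAo,manual,470,197,
4,2.38,UV,automated,385,162,-14.2
4,2.38,UV,manual,337,142,
6,2.52,DAo,manual,729,290,
6,2.52,UV,automated,411,163,-9.6
6,2.52,UV,manual,375,149,
7,2.57,DAo,automated,984,383,-6.0
7,2.57,DAo,manual,928,361,
7,2.57,UV,automated,397,154,1.2
7,2.57,UV,manual,402,156,
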