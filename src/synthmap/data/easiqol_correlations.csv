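instrument,PAIN-VAS,BASFI,BASDAI,ASQOL,SF36-PCS,SF36-MCS
PAIN-VAS,1,0.703,0.852,0.738,-0.668,-0.493
BASFI,0.703,1,0.811,0.829,-0.842,-0.463
BASDAI,0.852,0.811,1,0.856,-0.751,-0.583
ASQOL,0.738,0.829,0.856,1,-0.785,-0.654
SF36-PCS,-0.668,-0.842,-0.751,-0.785,1,0.339
SF36-MCS,-0.493,-0.463,-0.583,-0.654,0.339,1
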