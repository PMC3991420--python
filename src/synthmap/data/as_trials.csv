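trial_id,contrast_id,treatment_label,followup_weeks,instrument,effect,se
gorman-2002,1,etanercept 25 mg,16,PAIN-VAS,-4.15,0.803
gorman-2002,1,etanercept 25 mg,16,BASFI,-2.2,0.772
brandt-2003,1,etanercept 25 mg,6,BASFI,-1.7,0.80
brandt-2003,1,etanercept 25 mg,6,BASDAI,-2.2,0.553
davis-2003,1,etanercept 25 mg,24,PAIN-VAS,-1.83,0.410
davis-2003,1,etanercept 25 mg,24,BASFI,-1.41,0.285
davis-2003,1,etanercept 25 mg,24,BASDAI,-1.91,0.258
vanderheijde-2006,1,adalimumab 40 mg,12,PAIN-VAS,-1.956,0.350
vanderheijde-2006,1,adalimumab 40 mg,12,BASFI,-1.414,0.267
vanderheijde-2006,1,adalimumab 40 mg,12,BASDAI,-1.8,0.283
braun-2002,1,infliximab 5 mg,12,BASFI,-2.0,0.561
braun-2002,1,infliximab 5 mg,12,BASDAI,-2.6,0.433
braun-2002,1,infliximab 5 mg,12,SF36-PCS,8.3,5.74
braun-2002,1,infliximab 5 mg,12,SF36-MCS,3.85,4.33
vanderheijde-2005,1,adalimumab 40 mg,24,BASFI,-1.5,0.236
vanderheijde-2005,1,adalimumab 40 mg,24,BASDAI,-1.8,0.286
vanderheijde-2005,1,adalimumab 40 mg,24,ASQOL,-2.4,0.488
vanderheijde-2005,1,adalimumab 40 mg,24,SF36-PCS,5.2,1.026
vanderheijde-2005,1,adalimumab 40 mg,24,SF36-MCS,1.6,1.162
vanderheijde-2009,1,infliximab 5 mg,24,PAIN-VAS,-2.6,0.333
vanderheijde-2009,1,infliximab 5 mg,24,BASFI,-1.7,0.230
vanderheijde-2009,1,infliximab 5 mg,24,BASDAI,-2.5,0.274
vanderheijde-2009,1,infliximab 5 mg,24,SF36-PCS,9.4,0.957
vanderheijde-2009,1,infliximab 5 mg,24,SF36-MCS,0.7,1.045
inman-2008,1,golimumab 50 mg,12,PAIN-VAS,-2.7,0.412
inman-2008,1,golimumab 50 mg,12,BASFI,-1.5,0.264
inman-2008,1,golimumab 50 mg,12,SF36-PCS,4.9,1.164
inman-2008,1,golimumab 50 mg,12,SF36-MCS,1.4,1.023
inman-2008,2,golimumab 100 mg,12,PAIN-VAS,-2.8,0.424
inman-2008,2,golimumab 100 mg,12,BASFI,-1.6,0.274
inman-2008,2,golimumab 100 mg,12,SF36-PCS,6.0,1.069
inman-2008,2,golimumab 100 mg,12,SF36-MCS,3.6,1.252
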