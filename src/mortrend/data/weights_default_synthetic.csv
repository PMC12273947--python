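gc_group,sex,age_group,target_group,weight
undetermined_intent,male,10-14,suicide,0.30
undetermined_intent,male,10-14,homicide,0.45
undetermined_intent,male,10-14,other_accident,0.25
undetermined_intent,male,15-19,suicide,0.25
undetermined_intent,male,15-19,homicide,0.55
undetermined_intent,male,15-19,other_accident,0.20
undetermined_intent,female,10-14,suicide,0.35
undetermined_intent,female,10-14,homicide,0.35
undetermined_intent,female,10-14,other_accident,0.30
undetermined_intent,female,15-19,suicide,0.35
undetermined_intent,female,15-19,homicide,0.40
undetermined_intent,female,15-19,other_accident,0.25
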