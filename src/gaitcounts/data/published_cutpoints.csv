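placement,axis,epoch_length_s,t1,t2,t3
waist,v,15,41,372,502
waist,vm,15,140,572,990
ankle,v,15,184,1363,2851
ankle,vm,15,401,1862,3265
waist,v,60,270,1458,2055
waist,vm,60,491,2254,4058
ankle,v,60,570,4445,10793
ankle,vm,60,779,7200,12487
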