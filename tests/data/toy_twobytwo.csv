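id,kappa,t1,a1,t2,a2,u,delta,x1_age
s1,2,0,0,0.5,1,2.4,1,61
s2,1,0,1,,,0.3,0,47
s3,2,0,1,0.7,0,1.9,1,55
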