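source,model,factor_a,factor_b,value
caspi,revised_bifactor,Ext,Int,-0.471
simdata,revised_bifactor,Ext,Int,-0.387
caspi,correlated,Ext,Int,0.328
caspi,correlated,Ext,Tht,0.577
caspi,correlated,Int,Tht,0.849
simdata,correlated,Ext,Int,0.296
simdata,correlated,Ext,Tht,0.531
simdata,correlated,Int,Tht,0.869
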