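source,factor,VC,PR,WM,PS
caspi,p,-0.129,-0.129,-0.183,-0.176
caspi,Ext,-0.084,-0.054,-0.028,-0.035
caspi,Int,0.112,0.062,-0.027,0.019
simdata,p,-0.120,-0.123,-0.176,-0.167
simdata,Ext,-0.120,-0.068,-0.015,-0.035
simdata,Int,0.110,0.060,-0.007,0.032
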