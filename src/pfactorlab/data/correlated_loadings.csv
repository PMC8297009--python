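source,factor,alc,cann,hd,tob,cd,dep,gad,fears,ocd,mania,schiz
caspi,Ext,0.733,0.885,0.839,0.668,0.909,,,,,,
caspi,Int,,,,,,0.972,0.934,0.704,,,
caspi,Tht,,,,,,,,,0.726,0.982,0.826
simdata,Ext,0.604,0.678,0.652,0.545,0.694,,,,,,
simdata,Int,,,,,,0.682,0.677,0.563,,,
simdata,Tht,,,,,,,,,0.709,0.968,0.805
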