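source,factor,alc,cann,hd,tob,cd,dep,gad,fears,ocd,mania,schiz
caspi,p,0.397,0.455,0.452,0.504,0.557,0.835,0.812,0.623,0.725,0.973,0.819
caspi,Ext,0.626,0.811,0.709,0.420,0.691,,,,,,
caspi,Int,,,,,,0.340,0.497,0.441,,,
simdata,p,0.294,0.309,0.320,0.398,0.394,0.605,0.582,0.476,0.709,0.969,0.805
simdata,Ext,0.536,0.629,0.577,0.368,0.559,,,,,,
simdata,Int,,,,,,0.247,0.388,0.347,,,
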