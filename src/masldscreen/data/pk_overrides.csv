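compound,ka,cl,vd,f,mw,logp,tpsa
baicalin,0.8,0.1,0.62,,446.36,1.0,187.0
myricetin,0.8,0.1,0.632,,318.24,1.6,151.6
luteolin,0.8,0.1,0.648,,286.24,2.4,111.1
rutin,0.8,0.1,0.632,,610.52,1.6,269.4
diosmin,0.8,0.1,0.644,,608.54,2.2,269.4
genistein,0.8,0.1,0.64,0.135,270.24,2.0,90.9
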