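compound,mw,logp,tpsa
baicalin,446.36,1.0,187.0
myricetin,318.24,1.6,151.6
luteolin,286.24,2.4,111.1
rutin,610.52,1.6,269.4
diosmin,608.54,2.2,269.4
genistein,270.24,2.0,90.9
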