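target_id,role,weight
THRB,Regulation of basal metabolic rate and lipid metabolism,0.882
FXR,Bile acid and lipid metabolism regulator,0.736
FABP4,Intracellular fatty acid transport protein,0.875
PPARG,"Adipogenesis, glucose and lipid metabolism",0.922
PPARA,"Fatty acid oxidation, lipoprotein metabolism",0.924
HMGCR,Cholesterol biosynthesis rate-limiting enzyme,0.918
ACC1,Fatty acid synthesis rate-limiting enzyme,0.917
DGAT2,Triacylglycerol synthesis,0.558
LIPG,HDL metabolism (endothelial lipase),0.678
FASN,Synthesis of long-chain fatty acids,0.879
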