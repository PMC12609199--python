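form,compound,mw,logp,tpsa,stability_risks,carrier,flavor_profile
Morning,baicalin,446.36,1.0,187.0,pH-dependent glycosidic hydrolysis; photodegradation; oxidation of phenolic groups,Microencapsulation (maltodextrin/arabic gum); light-impermeable packaging,"bitter, herbal, astringent"
Morning,myricetin,318.24,1.6,151.6,Poor solubility; oxidation/darkening in aqueous systems; pH and temperature sensitivity,Liposomal/self-emulsifying systems; cyclodextrins; co-solvents (PEG),"bitter-astringent, floral-herbal"
Morning,luteolin,286.24,2.4,111.1,Low solubility; photolability; crystallization tendency,Solid dispersions; co-crystals; self-emulsifying phospholipid preparations,"bitter, astringent"
Evening,rutin,610.52,1.6,269.4,Poor aqueous solubility; acid-catalyzed deglycosylation; low permeability,Micronization + surfactants; polyglucosylation; hard gelatin capsule,"mild bitterness, astringent"
Evening,diosmin,608.54,2.2,269.4,Poor solubility and permeability; photolability,Nanosuspensions; cyclodextrin complexes; UV-barrier packaging,"bitter, slightly citrus/astringent"
Postprandial,genistein,270.24,2.0,90.9,Thermal degradation; oxidation; tautomeric/isomeric transitions,Protein-based matrices (soy isolate); film/chewable forms; antioxidant buffers,"bitter, bean-/nut-like"
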