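exosome
exosomes	exosome
exosomal	exosome
microvesicle
microvesicles	microvesicle
extracellular vesicle
extracellular vesicles	extracellular vesicle
vesicle
vesicles	vesicle
protein complex
high-density lipoprotein
HDL	high-density lipoprotein
lipoprotein
apoptotic body
apoptotic bodies	apoptotic body
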