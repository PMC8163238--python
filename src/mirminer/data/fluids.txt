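serum
plasma
seminal plasma
urine
saliva
blood
whole blood
cerebrospinal fluid
tear
tears
breast milk
milk
sputum
amniotic fluid
pleural effusion
semen
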