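# Small chemical-name lexicon for the dictionary entity masker.
# One name per line; multi-word names allowed. Lower-case matching.
midazolam
warfarin
digoxin
caffeine
theophylline
gentamicin
vancomycin
rifampicin
metformin
ibuprofen
paracetamol
acetaminophen
morphine
fentanyl
propofol
ketamine
lidocaine
amoxicillin
ciprofloxacin
fluconazole
itraconazole
cyclosporine
tacrolimus
sirolimus
methotrexate
carbamazepine
phenytoin
valproic acid
lithium carbonate
omeprazole
simvastatin
atorvastatin
amlodipine
losartan
enalapril
furosemide
insulin
heparin
dexamethasone
prednisolone
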