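# variant<TAB>canonical. British/American spelling variants and common
# pharmacology acronyms merged onto one canonical form.
tumour	tumor
tumours	tumors
anaemia	anemia
leukaemia	leukemia
haemorrhage	hemorrhage
haematology	hematology
oedema	edema
oesophagus	esophagus
diarrhoea	diarrhea
paediatric	pediatric
anaesthesia	anesthesia
foetal	fetal
favourable	favorable
behaviour	behavior
colour	color
labelled	labeled
randomised	randomized
hospitalisation	hospitalization
organisation	organization
utilisation	utilization
immunisation	immunization
sensitisation	sensitization
characterised	characterized
analysed	analyzed
centre	center
litre	liter
fibre	fiber
programme	program
adr	adverse_drug_reaction
adrs	adverse_drug_reaction
ae	adverse_event
aes	adverse_event
sae	serious_adverse_event
tnf	tumor_necrosis_factor
ra	rheumatoid_arthritis
ibd	inflammatory_bowel_disease
tb	tuberculosis
fda	food_and_drug_administration
ema	european_medicines_agency
rct	randomized_controlled_trial
ci	confidence_interval
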