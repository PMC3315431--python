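# Starter list of drug-class-agnostic (general) predictors: terms about
# safety signals, study design and regulatory action rather than any one
# drug class. Supply your own list to this loader to replace it.
adverse
adverse_event
adverse_drug_reaction
serious_adverse_event
safety
risk
reaction
toxicity
toxic
side effect
case report
case series
event
harm
hazard
injury
death
mortality
fatal
fatality
incidence
prevalence
surveillance
post marketing surveillance
pharmacovigilance
contraindication
warning
black box warning
precaution
label
withdrawal
discontinuation
overdose
interaction
complication
infection
opportunistic infection
malignancy
lymphoma
carcinogenic
teratogenic
congenital
abnormality
hepatotoxicity
nephrotoxicity
cardiotoxicity
neurotoxicity
hypersensitivity
anaphylaxis
allergy
allergic
rash
tolerability
tolerate
monitor
monitoring
report
reporting
signal
causality
causative
association
exposure
onset
severity
severe
dose
dosage
trial
clinical trial
randomized controlled trial
cohort
registry
observational
placebo
outcome
follow
efficacy
effectiveness
benefit
regulatory
agency
patient
treatment
therapy
mechanism
rare
unexpected
new
emergent
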