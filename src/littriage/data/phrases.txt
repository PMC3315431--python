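# Multiword terms counted as a single predictor (space-separated tokens).
tumor necrosis factor
adverse drug reaction
adverse event
serious adverse event
side effect
case report
case series
clinical trial
randomized controlled trial
confidence interval
risk factor
drug safety
post marketing surveillance
black box warning
heart failure
liver failure
renal failure
bone marrow
multiple sclerosis
crohn disease
ulcerative colitis
rheumatoid arthritis
ankylosing spondylitis
opportunistic infection
latent tuberculosis
injection site reaction
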