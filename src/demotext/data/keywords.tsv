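# Fixture health-keyword list: phrase <TAB> category (drug|hashtag|disorder|pharma|insurance).
# A 40-entry stand-in for a full representative keyword list; a complete
# list in the same two-column layout drops in unchanged.
lisinopril	drug
metformin	drug
lipitor	drug
plavix	drug
viagra	drug
xanax	drug
prozac	drug
adderall	drug
clomid	drug
oxycontin	drug
hydrocodone	drug
diovan	drug
concerta	drug
topamax	drug
synthroid	drug
#bcsm	hashtag
#hcsm	hashtag
#meded	hashtag
#flu	hashtag
#cancer	hashtag
aids	disorder
hiv	disorder
asthma	disorder
diabetes	disorder
cancer	disorder
migraine	disorder
fibromyalgia	disorder
depression	disorder
adhd	disorder
arthritis	disorder
cholesterol	disorder
insomnia	disorder
menopause	disorder
novartis	pharma
pfizer	pharma
merck	pharma
roche	pharma
aetna	insurance
cigna	insurance
humana	insurance
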