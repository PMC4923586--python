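# Fixture concept dictionary (synthetic stand-in for a UMLS-derived export):
# concept_id <TAB> preferred_name <TAB> synonyms ('|'-separated) <TAB> semantic_group
# Any UMLS-derived TSV in this layout drops in unchanged.
C0027051	Myocardial infarction	heart attack|myocardial infarction|MI	Disorders
C0018681	Headache	headache|headaches|head ache	Disorders
C0149931	Migraine disorders	migraine|migraines	Disorders
C0016053	Fibromyalgia	fibromyalgia|fibro	Disorders
C0011849	Diabetes mellitus	diabetes|diabetic	Disorders
C0004096	Asthma	asthma	Disorders
C0011570	Mental depression	depression|depressed mood	Disorders
C0003469	Anxiety disorder	anxiety|anxiety attack	Disorders
C0030193	Pain	pain	Disorders
C0004604	Back pain	back pain|backache	Disorders
C0024031	Low back pain	low back pain	Disorders
C0019158	Hepatitis	hepatitis	Disorders
C0019693	HIV seropositivity	hiv	Disorders
C0001175	Acquired immunodeficiency syndrome	aids|acquired immunodeficiency syndrome	Disorders
C0038454	Cerebrovascular accident	stroke|cerebrovascular accident	Disorders
C0004238	Atrial fibrillation	atrial fibrillation|afib	Disorders
C0020538	Hypertension	hypertension|high blood pressure	Disorders
C0014544	Epilepsy	epilepsy|seizures	Disorders
C0021400	Influenza	influenza|flu	Disorders
C0041296	Tuberculosis	tuberculosis	Disorders
C0006142	Breast cancer	breast cancer	Disorders
C0033578	Prostate cancer	prostate cancer	Disorders
C0029456	Osteoporosis	osteoporosis	Disorders
C0035222	Rheumatoid arthritis	rheumatoid arthritis	Disorders
C0409959	Endometriosis	endometriosis	Disorders
C0032460	Polycystic ovary syndrome	pcos|polycystic ovary syndrome	Disorders
C0015672	Chronic fatigue syndrome	chronic fatigue syndrome	Disorders
C0026769	Multiple sclerosis	multiple sclerosis|ms disorder	Disorders
C0001973	Alcoholism	alcoholism|alcohol abuse	Disorders
C0006870	Attention deficit hyperactivity disorder	adhd|attention deficit hyperactivity disorder	Disorders
C0021665	Insomnia	insomnia|sleeplessness	Disorders
C0025202	Melanoma	melanoma	Disorders
C0282488	Immunologic factor	i|immunologic factor	Chemicals & Drugs
C0065374	Lisinopril	lisinopril	Chemicals & Drugs
C0025598	Metformin	metformin	Chemicals & Drugs
C0593906	Lipitor	lipitor	Chemicals & Drugs
C0633084	Plavix	plavix	Chemicals & Drugs
C0663241	Viagra	viagra|sildenafil	Chemicals & Drugs
C0002600	Alprazolam	xanax|alprazolam	Chemicals & Drugs
C0162373	Fluoxetine	prozac|fluoxetine	Chemicals & Drugs
C0699680	Adderall	adderall	Chemicals & Drugs
C0009010	Clomiphene	clomid|clomiphene	Chemicals & Drugs
C0702163	Oxycontin	oxycontin|oxycodone	Chemicals & Drugs
C0020264	Hydrocodone	hydrocodone	Chemicals & Drugs
C1170019	Diovan	diovan|valsartan	Chemicals & Drugs
C0729659	Concerta	concerta	Chemicals & Drugs
C0733419	Topamax	topamax|topiramate	Chemicals & Drugs
C0728762	Ibuprofen	ibuprofen|advil	Chemicals & Drugs
C0699142	Tylenol	tylenol|acetaminophen	Chemicals & Drugs
C0042890	Vitamins	vitamin|vitamins	Chemicals & Drugs
C0086418	Human	human|person	Living Beings
C0018787	Heart	heart	Anatomy
C0023884	Liver	liver	Anatomy
C0037303	Brain	brain	Anatomy
C0199168	Medical consultation	doctor visit	Procedures
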