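# Demonstration condition lexicon: concept_id<TAB>synonym, one per line.
lactose intolerance	dairy intolerance
lactose intolerance	lactose intolerant
inflammatory bowel disease	ibd
malabsorption	malabsorption syndrome
peptic ulcer	stomach ulcer
irritable bowel syndrome	ibs
irritable bowel syndrome	spastic colon
food intolerance	food sensitivity
crohn disease	crohns disease
crohn disease	crohn s disease
digestive disease	digestive disorder
polycystic ovary syndrome	pcos
peritonitis	abdominal infection
autoimmunity	autoimmune disease
autoimmunity	autoimmune disorder
attention deficit hyperactivity disorder	adhd
attention deficit hyperactivity disorder	attention deficit disorder
hypothyroidism	underactive thyroid
gastroesophageal reflux disease	gerd
gastroesophageal reflux disease	acid reflux
asthma	asthmatic
influenza	flu
influenza	the flu
migraine	migraines
colitis	microscopic colitis
systemic lupus erythematosus	lupus
alzheimer disease	alzheimers
alzheimer disease	alzheimer s disease
diabetes	type 2 diabetes
hypertension	high blood pressure
anemia	iron deficiency
osteoporosis	brittle bones
eczema	atopic dermatitis
psoriasis	plaque psoriasis
gout	gouty arthritis
pneumonia	lung infection
bronchitis	chest infection
appendicitis	inflamed appendix
gallstones	gallbladder stones
kidney stones	renal calculi
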