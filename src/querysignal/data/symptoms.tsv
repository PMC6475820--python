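# Demonstration symptom lexicon: concept_id<TAB>synonym, one per line.
# Every concept id is implicitly its own synonym.
diarrhea	loose stools
diarrhea	watery stools
diarrhea	diarrhoea
steatorrhea	fatty stools
steatorrhea	oily stools
dyspepsia	indigestion
dyspepsia	upset stomach
exophthalmos	bulging eyes
vomiting	throwing up
vomiting	emesis
stomach ache	stomachache
stomach ache	tummy ache
xerostomia	dry mouth
flatulence	excessive gas
flatulence	passing gas
abdominal pain	belly pain
abdominal pain	stomach cramps
bloating	bloated stomach
bloating	abdominal distension
cough	coughing
headache	head ache
headache	head pain
anxiety	anxious
anxiety	panic attacks
bleeding	blood loss
weight loss	losing weight
weight loss	unintentional weight loss
depression	depressed
depression	feeling down
pain	aches
itch	itching
itch	pruritus
fatigue	tiredness
fatigue	exhaustion
nausea	feeling sick
rash	skin rash
fever	high temperature
dizziness	lightheadedness
constipation	hard stools
joint pain	sore joints
numbness	tingling
insomnia	sleeplessness
hair loss	losing hair
sore throat	throat pain
heartburn	acid indigestion
mouth ulcers	canker sores
back pain	backache
muscle cramps	leg cramps
night sweats	sweating at night
shortness of breath	breathlessness
swollen ankles	ankle swelling
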