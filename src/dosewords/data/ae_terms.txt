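# Potential adverse-event terms, one single-token term per line.
# Matching is case-insensitive on whole whitespace-delimited tokens.
tremor
sedation
akathisia
dystonia
dyskinesia
rigidity
parkinsonism
bradykinesia
akinesia
dizziness
drowsiness
somnolence
lethargy
fatigue
constipation
nausea
vomiting
dyspepsia
hypersalivation
drooling
xerostomia
galactorrhea
amenorrhea
gynecomastia
hyperprolactinemia
hyperglycemia
dyslipidemia
hypotension
hypertension
tachycardia
bradycardia
palpitations
syncope
seizure
headache
insomnia
nightmares
restlessness
stiffness
dysphagia
dysarthria
diplopia
photosensitivity
rash
pruritus
urticaria
neutropenia
leukopenia
agranulocytosis
myocarditis
fever
enuresis
incontinence
priapism
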