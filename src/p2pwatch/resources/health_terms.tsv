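# Patient-oriented health term sources: raw term<TAB>category.
# A small stand-in for ICD/MedDRA-derived disease and symptom lists, a
# national drug product database, and manually collected acronyms,
# specialties and condition names. Terms are normalized at load time
# (lowercased, punctuation and digits stripped, stop words removed).
arthritis	disease
rheumatoid arthritis	disease
mumps	disease
measles	disease
chickenpox	disease
asthma	disease
diabetes	disease
cancer	disease
leukemia	disease
lymphoma	disease
melanoma	disease
pneumonia	disease
influenza	disease
tuberculosis	disease
hepatitis	disease
cirrhosis	disease
epilepsy	disease
migraine	disease
eczema	disease
psoriasis	disease
bronchitis	disease
sinusitis	disease
tonsillitis	disease
appendicitis	disease
meningitis	disease
hypertension	disease
hypothyroidism	disease
osteoporosis	disease
anemia	disease
sepsis	disease
shingles	disease
malaria	disease
depression	disease
schizophrenia	disease
bipolar disorder	disease
anxiety disorder	disease
dementia	disease
parkinson disease	disease
alzheimer disease	disease
crohn disease	disease
celiac disease	disease
cystic fibrosis	disease
multiple sclerosis	disease
muscular dystrophy	disease
glaucoma	disease
cataract	disease
gout	disease
ulcer	disease
stroke	disease
angina	disease
arrhythmia	disease
chest pain	symptom
headache	symptom
fever	symptom
nausea	symptom
vomiting	symptom
fatigue	symptom
dizziness	symptom
rash	symptom
sore throat	symptom
back pain	symptom
joint pain	symptom
abdominal pain	symptom
shortness of breath	symptom
wheezing	symptom
numbness	symptom
swelling	symptom
seizure	symptom
insomnia	symptom
palpitations	symptom
heartburn	symptom
constipation	symptom
diarrhea	symptom
heart surgery	procedure
bypass surgery	procedure
x-ray	procedure
ultrasound	procedure
chemotherapy	procedure
radiotherapy	procedure
dialysis	procedure
biopsy	procedure
blood test	procedure
blood transfusion	procedure
vaccination	procedure
immunization	procedure
transplant	procedure
mammogram	procedure
colonoscopy	procedure
endoscopy	procedure
angioplasty	procedure
hip replacement	procedure
knee replacement	procedure
appendectomy	procedure
tonsillectomy	procedure
cesarean section	procedure
physiotherapy	procedure
acetaminophen	drug_generic
ibuprofen	drug_generic
naproxen	drug_generic
insulin	drug_generic
metformin	drug_generic
warfarin	drug_generic
heparin	drug_generic
penicillin	drug_generic
amoxicillin	drug_generic
azithromycin	drug_generic
ciprofloxacin	drug_generic
prednisone	drug_generic
morphine	drug_generic
codeine	drug_generic
oxycodone	drug_generic
fluoxetine	drug_generic
sertraline	drug_generic
lorazepam	drug_generic
diazepam	drug_generic
atorvastatin	drug_generic
simvastatin	drug_generic
lisinopril	drug_generic
amlodipine	drug_generic
levothyroxine	drug_generic
omeprazole	drug_generic
salbutamol	drug_generic
methotrexate	drug_generic
tamoxifen	drug_generic
Tylenol	drug_trade
Advil	drug_trade
Aspirin	drug_trade
Motrin	drug_trade
Aleve	drug_trade
Lipitor	drug_trade
Crestor	drug_trade
Prozac	drug_trade
Zoloft	drug_trade
Paxil	drug_trade
Xanax	drug_trade
Valium	drug_trade
Ativan	drug_trade
Ventolin	drug_trade
Claritin	drug_trade
Benadryl	drug_trade
Ritalin	drug_trade
Adderall	drug_trade
Coumadin	drug_trade
Glucophage	drug_trade
Synthroid	drug_trade
Nexium	drug_trade
Prilosec	drug_trade
Viagra	drug_trade
Lantus	drug_trade
Humira	drug_trade
ICU	acronym
MRI	acronym
CT scan	acronym
ECG	acronym
EKG	acronym
EEG	acronym
HIV	acronym
AIDS	acronym
COPD	acronym
ADHD	acronym
PTSD	acronym
CPR	acronym
DNR	acronym
OCD	acronym
IBS	acronym
UTI	acronym
therapist	specialty
surgeon	specialty
cardiologist	specialty
oncologist	specialty
neurologist	specialty
radiologist	specialty
psychiatrist	specialty
pediatrician	specialty
dermatologist	specialty
anesthesiologist	specialty
physiotherapist	specialty
midwife	specialty
paramedic	specialty
blood pressure	condition
tube fed	condition
overweight	condition
obesity	condition
malnutrition	condition
dehydration	condition
concussion	condition
fracture	condition
sprain	condition
allergy	condition
infection	condition
inflammation	condition
remission	condition
relapse	condition
chronic pain	condition
bed rest	condition
intensive care	condition
life support	condition
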