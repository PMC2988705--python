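# Known-lemma lexicon used to validate candidates produced by the
# suffix-rule cascade.  One lowercase lemma per line; '#' starts a comment.
# Covers the packaged fixture vocabulary plus common clinical words.
abdomen
abnormal
acetabular
acinetobacter
acute
agree
albumin
alopecia
aluminum
amylase
anemia
ankle
antibiotic
anticoagulant
anticonvulsant
antidepressant
antihypertensive
antimony
anxiety
arthralgia
asthenia
bacteremia
bilirubin
bladder
blood
bone
bradycardia
brain
breast
bronchodilator
calcium
candida
carcinoma
cardiac
cataract
cerebral
chest
cholesterol
chorioretinitis
chronic
colitis
congenital
constipation
cortisol
cough
creatinine
cutaneous
cytomegalovirus
decrease
dermatitis
diarrhea
diphtheria
diphtheritic
disease
disorder
diuretic
dizziness
drug
dysphemia
dysplasia
dyspnea
edema
elbow
elevate
endocarditis
enterococcus
epistaxis
escherichia
esophagus
fatigue
feces
feel
ferritin
fever
find
finding
foot
forearm
gastric
gastritis
glioma
glucose
guilt
headache
heart
hematocrit
hematuria
hemoglobin
hepatic
hepatitis
high
hip
immunosuppressant
increase
infection
inflammation
influenza
injury
insomnia
intermittent
kidney
klebsiella
knee
label
leaf
leave
lenticular
leukemia
level
lipase
listeria
lithium
liver
low
lung
lymphoma
magnesium
malaise
malaria
man
measles
measurement
melanoma
meningitis
mesothelioma
metastasis
metastatic
migraine
mild
mouse
myalgia
myeloma
myocarditis
nausea
negative
neoplasm
neuropathy
normal
off
organism
pain
palpitation
pancreas
paresthesia
persistent
phosphate
plasma
platelet
pneumonia
positive
potassium
prolactin
prophylaxis
proteinuria
proteus
pruritus
pseudomonas
pulmonary
rabies
rash
record
recurrent
renal
result
salmonella
sarcoma
scalp
sepsis
serratia
serum
severe
shoulder
skin
sodium
somnolence
species
spine
spleen
stage
staphylococcus
stomach
streptococcus
stutter
supportive
swell
syncope
tachycardia
term
test
tetanus
therapeutic
therapy
thigh
thyroid
tinnitus
tooth
toxic
toxicity
transient
tremor
troponin
tuberculosis
tumor
urate
urticaria
use
vertigo
virus
woman
wrist
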