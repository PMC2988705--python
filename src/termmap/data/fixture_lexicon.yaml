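# Word lexicon for the synthetic-terminology generator.  Stems are grouped
# by the semantic categories the compositional pattern grammar needs; each
# stem is used for at most one generated concept so planted ground truth is
# unambiguous.
categories:
  LAB_TEST:
    - hematocrit
    - hemoglobin
    - sodium
    - potassium
    - calcium
    - glucose
    - digoxin
    - creatinine
    - bilirubin
    - albumin
    - platelet
    - lithium
    - magnesium
    - phosphate
    - urate
    - cortisol
    - prolactin
    - ferritin
    - troponin
    - amylase
    - lipase
    - cholesterol
  QUALIFIER:
    - abnormal
    - normal
    - increased
    - decreased
    - high
    - low
    - positive
    - negative
    - elevated
  ORGANISM:
    - escherichia
    - staphylococcus
    - streptococcus
    - klebsiella
    - pseudomonas
    - candida
    - salmonella
    - enterococcus
    - listeria
    - proteus
    - serratia
    - acinetobacter
  MALIGNANCY:
    - lymphoma
    - melanoma
    - carcinoma
    - sarcoma
    - leukemia
    - myeloma
    - glioma
    - mesothelioma
  PHARM_ACTION:
    - anticonvulsant
    - anticoagulant
    - antibiotic
    - antidepressant
    - antihypertensive
    - diuretic
    - immunosuppressant
    - bronchodilator
  DISEASE:
    - malaria
    - tuberculosis
    - influenza
    - tetanus
    - rabies
    - measles
    - hepatitis
    - pneumonia
    - meningitis
    - endocarditis
  BODY_PART:
    - shoulder
    - knee
    - elbow
    - wrist
    - ankle
    - hip
    - spine
    - abdomen
    - chest
    - thigh
    - forearm
    - scalp
  ORGAN_SYSTEM:
    - liver
    - kidney
    - lung
    - heart
    - pancreas
    - spleen
    - thyroid
    - bladder
    - brain
  OTHER:
    - headache
    - nausea
    - fatigue
    - dizziness
    - rash
    - pruritus
    - edema
    - anemia
    - syncope
    - insomnia
    - tremor
    - vertigo
    - dyspnea
    - cough
    - fever
    - malaise
    - anxiety
    - dermatitis
    - gastritis
    - neuropathy
    - myalgia
    - arthralgia
    - alopecia
    - urticaria
    - epistaxis
    - tinnitus
    - palpitation
    - constipation
    - diarrhea
    - hematuria
    - proteinuria
    - bradycardia
    - tachycardia
    - asthenia
    - paresthesia
    - somnolence
    - migraine
    - colitis

# Single-word concepts always generated first within OTHER so that every
# pattern trigger has a coverable target concept.
triggers:
  - infection
  - bacteremia
  - sepsis
  - stage
  - recurrent
  - metastatic
  - therapy
  - prophylaxis
  - pain
  - inflammation
  - injury
  - toxicity

# Modifiers used to build two-word variants of OTHER concepts.
modifiers:
  - chronic
  - acute
  - severe
  - mild
  - transient
  - intermittent
  - persistent

# American -> British respelling pairs used by the planted-duplicate
# generator (each is the inverse of a rule or exception in the spelling
# normalizer).
british:
  hematocrit: haematocrit
  hemoglobin: haemoglobin
  anemia: anaemia
  leukemia: leukaemia
  diarrhea: diarrhoea
  edema: oedema
  dyspnea: dyspnoea
  hematuria: haematuria
  tumor: tumour
  aluminum: aluminium
  esophagus: oesophagus
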