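# Composition-pattern grammar for classifying multi-concept mappings.
# Rules are tried in order; the first whose category appears among the
# cover's concepts AND whose trigger literal occurs in the source term wins.
- name: LAB_QUALIFIER
  category: LAB_TEST
  triggers: [normal, abnormal, increased, decreased, high, low, positive, negative, elevated]
- name: ORGANISM_INFECTION
  category: ORGANISM
  triggers: [infection, bacteremia, sepsis]
- name: MALIGNANCY_STAGE
  category: MALIGNANCY
  triggers: [stage, recurrent, metastatic]
- name: PHARM_THERAPY
  category: PHARM_ACTION
  triggers: [therapy, supportive care]
- name: DISEASE_PROPHYLAXIS
  category: DISEASE
  triggers: [prophylaxis]
- name: BODYPART_PAIN
  category: BODY_PART
  triggers: [pain, inflammation, injury]
- name: ORGAN_TOXICITY
  category: ORGAN_SYSTEM
  triggers: [toxicity]
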