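# Greco-Latin / common-word equivalences used for query expansion and for
# canonicalizing audit keys.  Two columns per line (tab separated); the
# transitive closure of all pairs is taken at load time.
hepatic	liver
gastric	stomach
neoplasm	tumor
renal	kidney
cardiac	heart
pulmonary	lung
cerebral	brain
cutaneous	skin
diphtheria	diphtheritic
dysphemia	stutter
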