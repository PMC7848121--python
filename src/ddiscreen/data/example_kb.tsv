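drug_a	drug_b	severity	effect_text	effect_terms	mechanism_note
LANSOPRAZOLE	WARFARIN	major	Elevated INR and potentiation of anticoagulation effects	INTERNATIONAL_NORMALISED_RATIO_INCREASED;GASTROINTESTINAL_HAEMORRHAGE;CEREBRAL_HAEMORRHAGE;CONJUNCTIVAL_HAEMORRHAGE;HAEMATOMA;HAEMATURIA;HAEMORRHAGE	synthetic entry: CYP-mediated reduced warfarin clearance
ASPIRIN	CLOPIDOGREL	major	Increased risk of bleeding	GASTROINTESTINAL_HAEMORRHAGE;HAEMATOMA;CEREBRAL_HAEMORRHAGE;HAEMATURIA;HAEMORRHAGE	synthetic entry: additive platelet inhibition
ASPIRIN	WARFARIN	major	Increased risk of bleeding	GASTROINTESTINAL_HAEMORRHAGE;CEREBRAL_HAEMORRHAGE;HAEMATOMA;HAEMORRHAGE;INTERNATIONAL_NORMALISED_RATIO_INCREASED	synthetic entry: antiplatelet plus anticoagulant
ALLOPURINOL	WARFARIN	major	Increased INR	INTERNATIONAL_NORMALISED_RATIO_INCREASED;GASTROINTESTINAL_HAEMORRHAGE;HAEMATURIA;CEREBRAL_HAEMORRHAGE;HAEMATOMA	synthetic entry: inhibition of warfarin metabolism
OMEPRAZOLE	WARFARIN	major	Elevated INR and potentiation of anticoagulant effects	INTERNATIONAL_NORMALISED_RATIO_INCREASED;GASTROINTESTINAL_HAEMORRHAGE;CEREBRAL_HAEMORRHAGE;HAEMATOMA;MEDIASTINAL_HAEMORRHAGE	synthetic entry: CYP2C19-mediated
ASPIRIN	FUROSEMIDE	moderate	Reduced diuretic effectiveness and possible nephrotoxicity	ACUTE_KIDNEY_INJURY;RENAL_FAILURE	synthetic entry: prostaglandin inhibition
CLOPIDOGREL	WARFARIN	major	Increased risk of bleeding	GASTROINTESTINAL_HAEMORRHAGE;CEREBRAL_HAEMORRHAGE;INTERNATIONAL_NORMALISED_RATIO_INCREASED;HAEMORRHAGE	synthetic entry: additive haemorrhagic risk
DIGOXIN	FUROSEMIDE	major	Digoxin toxicity (nausea, vomiting, cardiac arrhythmias)	BRADYCARDIA;NAUSEA;VOMITING;ARRHYTHMIA;DIGOXIN_TOXICITY	synthetic entry: diuretic-induced hypokalaemia
ACETAMINOPHEN	WARFARIN	major	Increased risk of bleeding	GASTROINTESTINAL_HAEMORRHAGE;CEREBRAL_HAEMORRHAGE;HAEMORRHAGE;INTERNATIONAL_NORMALISED_RATIO_INCREASED;MEDIASTINAL_HAEMORRHAGE	synthetic entry: vitamin K cycle interference
QUETIAPINE	WARFARIN	moderate	Increased INR and risk of bleeding	GASTROINTESTINAL_HAEMORRHAGE;CEREBRAL_HAEMORRHAGE;HAEMATURIA;INTERNATIONAL_NORMALISED_RATIO_INCREASED	synthetic entry: protein-binding displacement
TRAZODONE	WARFARIN	moderate	Increased risk of bleeding	GASTROINTESTINAL_HAEMORRHAGE;CEREBRAL_HAEMORRHAGE;INTERNATIONAL_NORMALISED_RATIO_INCREASED	synthetic entry: serotonergic platelet impairment
ENOXAPARIN	WARFARIN	major	Increased risk of bleeding	GASTROINTESTINAL_HAEMORRHAGE;ARTERIAL_HAEMORRHAGE;HAEMATURIA;INTRA_ABDOMINAL_HAEMATOMA;HAEMORRHAGE	synthetic entry: dual anticoagulation
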