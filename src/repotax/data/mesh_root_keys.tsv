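C01	Bacterial Infections and Mycoses
C02	Virus Diseases
C03	Parasitic Diseases
C04	Neoplasms
C06	Digestive System Diseases
C07	Stomatognathic Diseases
C08	Respiratory Tract Diseases
C10	Nervous System Diseases
C11	Eye Diseases
C12	Male Urogenital Diseases
C13	Female Urogenital Diseases and Pregnancy Complications
C14	Cardiovascular Diseases
C15	Hemic and Lymphatic Diseases
C16	Congenital, Hereditary, and Neonatal Diseases and Abnormalities
C17	Skin and Connective Tissue Diseases
C18	Nutritional and Metabolic Diseases
C19	Endocrine System Diseases
C20	Immune System Diseases
C23	Pathological Conditions, Signs and Symptoms
C25	Chemically-Induced Disorders
E01	Diagnosis
F01	Behaviour Mechanisms
F03	Mental Disorders
G07	Physiological Processes
G08	Reproductive and Urinary Physiological Phenomena
G11	Musculoskeletal and Neural Physiological Phenomena
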