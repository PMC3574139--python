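aapp	Amino Acid, Peptide, or Protein
acab	Acquired Abnormality
anab	Anatomical Abnormality
bdsy	Body System
blor	Body Location or Region
bmod	Biomedical Occupation or Discipline
bpoc	Body Part, Organ, or Organ Component
diap	Diagnostic Procedure
dsyn	Disease or Syndrome
horm	Hormone
lbpr	Laboratory Procedure
imft	Immunologic Factor
inpo	Injury or Poisoning
mobd	Mental or Behavioral Dysfunction
neop	Neoplastic Process
orch	Organic Chemical
patf	Pathologic Function
phsu	Pharmacologic Substance
sosy	Sign or Symptom
topp	Therapeutic or Preventive Procedure
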