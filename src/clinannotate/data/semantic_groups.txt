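# Default semantic-group table (NLM SemGroups layout, abridged).
# GroupAbbrev|GroupName|TypeCode|TypeName
ANAT|Anatomy|T017|Anatomical Structure
ANAT|Anatomy|T023|Body Part, Organ, or Organ Component
ANAT|Anatomy|T024|Tissue
ANAT|Anatomy|T025|Cell
ANAT|Anatomy|T029|Body Location or Region
CHEM|Chemicals & Drugs|T103|Chemical
CHEM|Chemicals & Drugs|T109|Organic Chemical
CHEM|Chemicals & Drugs|T116|Amino Acid, Peptide, or Protein
CHEM|Chemicals & Drugs|T121|Pharmacologic Substance
CHEM|Chemicals & Drugs|T123|Biologically Active Substance
CHEM|Chemicals & Drugs|T200|Clinical Drug
DEVI|Devices|T074|Medical Device
DEVI|Devices|T075|Research Device
DISO|Disorders|T019|Congenital Abnormality
DISO|Disorders|T020|Acquired Abnormality
DISO|Disorders|T033|Finding
DISO|Disorders|T037|Injury or Poisoning
DISO|Disorders|T046|Pathologic Function
DISO|Disorders|T047|Disease or Syndrome
DISO|Disorders|T048|Mental or Behavioral Dysfunction
DISO|Disorders|T184|Sign or Symptom
DISO|Disorders|T191|Neoplastic Process
GENE|Genes & Molecular Sequences|T028|Gene or Genome
GENE|Genes & Molecular Sequences|T086|Nucleotide Sequence
LIVB|Living Beings|T005|Virus
LIVB|Living Beings|T007|Bacterium
LIVB|Living Beings|T016|Human
PHYS|Physiology|T039|Physiologic Function
PHYS|Physiology|T040|Organism Function
PROC|Procedures|T059|Laboratory Procedure
PROC|Procedures|T060|Diagnostic Procedure
PROC|Procedures|T061|Therapeutic or Preventive Procedure
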