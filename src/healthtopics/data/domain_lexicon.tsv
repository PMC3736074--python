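# Fixture medical-domain lexicon (synthetic mini-lexicon; not derived from UMLS data).
# Format: term<TAB>semantic-type code, one row per (term, code) pair.
# Terms are lowercase 1-3 word phrases; codes are the 20 health-related
# semantic-type abbreviations (Aapp..Topp) used for lexicon filtering.
estrogen receptor	Aapp
her2 protein	Aapp
progesterone receptor	Aapp
growth factor	Aapp
antibody	Aapp
cytokine	Aapp
insulin	Aapp
hemoglobin	Aapp
albumin	Aapp
collagen	Aapp
lymphedema	Acab
scar tissue	Acab
seroma	Acab
contracture	Acab
stenosis	Acab
adhesion	Acab
fibrosis	Acab
atrophy	Acab
hernia	Acab
keloid	Acab
cyst	Anab
calcification	Anab
dense tissue	Anab
ductal abnormality	Anab
polyp	Anab
lesion	Anab
nodule	Anab
mass	Anab
asymmetry	Anab
distortion	Anab
lymphatic system	Bdsy
immune system	Bdsy
endocrine system	Bdsy
nervous system	Bdsy
circulatory system	Bdsy
digestive system	Bdsy
respiratory system	Bdsy
skeletal system	Bdsy
reproductive system	Bdsy
urinary system	Bdsy
left breast	Blor
right breast	Blor
chest wall	Blor
upper arm	Blor
armpit	Blor
abdomen	Blor
pelvis	Blor
scalp	Blor
collarbone area	Blor
lower back	Blor
oncology	Bmod
radiology	Bmod
pathology	Bmod
surgery	Bmod
nursing	Bmod
pharmacy	Bmod
physical therapy	Bmod
genetics	Bmod
immunology	Bmod
psychiatry	Bmod
lymph node	Bpoc
breast	Bpoc
ovary	Bpoc
liver	Bpoc
lung	Bpoc
bone marrow	Bpoc
thyroid	Bpoc
uterus	Bpoc
milk duct	Bpoc
nipple	Bpoc
mammogram	Diap
biopsy	Diap
ultrasound	Diap
mri	Diap
pet scan	Diap
ct scan	Diap
bone scan	Diap
blood test	Diap
genetic testing	Diap
needle aspiration	Diap
breast cancer	Dsyn
diabetes	Dsyn
hypertension	Dsyn
osteoporosis	Dsyn
anemia	Dsyn
hypothyroidism	Dsyn
arthritis	Dsyn
pneumonia	Dsyn
shingles	Dsyn
migraine	Dsyn
estrogen	Horm
progesterone	Horm
testosterone	Horm
cortisol	Horm
thyroxine	Horm
prolactin	Horm
oxytocin	Horm
melatonin	Horm
adrenaline	Horm
oestradiol	Horm
interferon	Imft
interleukin	Imft
vaccine	Imft
immunoglobulin	Imft
antigen	Imft
immune booster	Imft
tumor antigen	Imft
allergen	Imft
immunosuppressant	Imft
adjuvant	Imft
radiation burn	Inpo
needle injury	Inpo
overdose	Inpo
chemical burn	Inpo
fracture	Inpo
bruising	Inpo
sprain	Inpo
laceration	Inpo
poisoning	Inpo
whiplash	Inpo
blood count	Lbpr
tumor marker	Lbpr
ca 125	Lbpr
liver panel	Lbpr
urinalysis	Lbpr
lipid panel	Lbpr
biomarker assay	Lbpr
hormone assay	Lbpr
culture test	Lbpr
white count	Lbpr
depression	Mobd
anxiety	Mobd
insomnia	Mobd
panic attack	Mobd
chemo brain	Mobd
ptsd	Mobd
mood swing	Mobd
memory loss	Mobd
brain fog	Mobd
burnout	Mobd
tumor	Neop
carcinoma	Neop
metastasis	Neop
dcis	Neop
sarcoma	Neop
lymphoma	Neop
melanoma	Neop
invasive carcinoma	Neop
recurrence	Neop
micrometastasis	Neop
taxol	Orch
carboplatin	Orch
cyclophosphamide	Orch
doxorubicin	Orch
fluorouracil	Orch
methotrexate	Orch
paclitaxel	Orch
epirubicin	Orch
capecitabine	Orch
gemcitabine	Orch
inflammation	Patf
necrosis	Patf
edema	Patf
ischemia	Patf
hyperplasia	Patf
dysplasia	Patf
thrombosis	Patf
infection	Patf
ulceration	Patf
degeneration	Patf
tamoxifen	Phsu
herceptin	Phsu
arimidex	Phsu
femara	Phsu
aromasin	Phsu
zoladex	Phsu
ibuprofen	Phsu
morphine	Phsu
steroid	Phsu
antibiotic	Phsu
fatigue	Sosy
nausea	Sosy
hot flash	Sosy
hair loss	Sosy
neuropathy	Sosy
joint pain	Sosy
swelling	Sosy
dizziness	Sosy
night sweat	Sosy
tenderness	Sosy
chemotherapy	Topp
mastectomy	Topp
lumpectomy	Topp
radiation therapy	Topp
reconstruction	Topp
hormone therapy	Topp
chemo	Topp
radiotherapy	Topp
immunotherapy	Topp
targeted therapy	Topp
tamoxifen	Orch
chemo	Phsu
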