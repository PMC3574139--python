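pain	sosy
symptoms	sosy
cough	sosy
coughing	sosy
breathless	sosy
chest pain	sosy
painful	sosy
shortness of breath	sosy
coughing up blood	sosy
short of breath	sosy
wheezing	sosy
nausea	sosy
sore	sosy
nipple discharge	sosy
breast pain	sosy
itching	sosy
itchy	sosy
tingling	sosy
hot flashes	sosy
tired	sosy
thirsty	sosy
fatigue	sosy
frequent urination	sosy
hungry	sosy
dizzy	sosy
pneumonia	dsyn
infection	dsyn|patf
tuberculosis	dsyn
bronchitis	dsyn
asthma	dsyn
copd	dsyn
pleural effusion	dsyn
emphysema	dsyn
atelectasis	patf
collapsed lung	patf
lymph edema	dsyn
rash	dsyn
fibrocystic breast	dsyn
mastitis	dsyn
eczema	dsyn
complex cyst	anab
paget's disease	dsyn
neuropathy	dsyn
fibrocystic disease	dsyn
hypoglycaemia	dsyn|patf
low blood sugar	patf
dka	dsyn
pcos	dsyn
coma	dsyn
kidney disease	dsyn
obesity	dsyn
diabetic neuropathy	dsyn
fever	sosy
cat scan	diap
biopsy	diap
x-ray	diap
pet scan	diap
chest x-ray	diap
scans	diap
mri	diap
bronchoscopy	diap
imaging	diap
biopsy needle	diap
mammogram	diap
ultrasound	diap
bi-rads	diap
core biopsy	diap
screening	diap
blood test	lbpr
fasting test	lbpr
glucose test	lbpr
fasting blood sugar	lbpr
hemoglobin a1c test	lbpr
glucose tolerance test	lbpr
gtts	lbpr
chemo	topp
radiation	topp
chemotherapy	topp
lobectomy	topp
operation	topp
therapy	topp
surgery	topp
removal	topp
radiation therapy	topp
wedge resection	topp
mastectomy	topp
lumpectomy	topp
implant	topp
radiotherapy	topp
surgical	topp
infusion	topp
injection	topp
transplant	topp
dialysis	topp
amputation	topp
insulin injection	topp
silicas	phsu
tarceva	phsu|orch
morphine	phsu|orch
chantix	phsu
carboplatin	phsu|orch
coumadin	phsu|orch
alimta	phsu
advil	phsu|orch
taxol	phsu|orch
dilaudid	phsu
tamoxifen	phsu|orch
arimidex	phsu
femara	phsu
taxotere	phsu
effexor	phsu
raloxifene	phsu|orch
valium	phsu|orch
docetaxel	phsu|orch
insulin	phsu|horm|aapp
lantus	phsu
metformin	phsu|orch
januvia	phsu
glucophage	phsu
actos	phsu
marihuana	phsu
avandia	phsu
glipizide	phsu|orch
amaryl	phsu
lung	bpoc
breast	bpoc
chest	blor
kidney	bpoc
pancreas	bpoc
lymph node	bpoc
blood sugar	lbpr
glucose	orch|phsu
hormone	horm
estrogen	horm|phsu
tumor	neop
cancer	neop
lung cancer	neop
breast cancer	neop
diabetes	dsyn
depression	mobd
anxiety	mobd
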