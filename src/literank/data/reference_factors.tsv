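# Reference factor list (version 1): common disease-associated factors
# curated by medical experts, spanning diseases/medical conditions,
# signs/symptoms, chemical compounds and environmental/lifestyle factors.
# Columns: name, category, query_terms (semicolon-joined synonyms).
asthma	disease/medical condition	asthma
autism	disease/medical condition	autism
schizophrenia	disease/medical condition	schizophrenia
HIV	disease/medical condition	HIV
immunological disorder	disease/medical condition	immunological disorder
bipolar	disease/medical condition	bipolar
hypertension	disease/medical condition	hypertension
osteoporosis	disease/medical condition	osteoporosis
coronary heart disease	disease/medical condition	coronary heart disease;CHD
diabetes	disease/medical condition	diabetes
allergy	disease/medical condition	allergy
herpes	disease/medical condition	herpes
leukemia	disease/medical condition	leukemia
breast cancer	disease/medical condition	breast cancer
lymphoma	disease/medical condition	lymphoma
hypothyroidism	disease/medical condition	hypothyroidism
hyperthyroidism	disease/medical condition	hyperthyroidism
insomnia	disease/medical condition	insomnia
depression	disease/medical condition	depression
viral infection	disease/medical condition	viral infection
bacterial infection	disease/medical condition	bacterial infection
hepatitis B virus	disease/medical condition	hepatitis B virus
retrovirus	disease/medical condition	retrovirus
enterovirus	disease/medical condition	enterovirus
morning cortisol level	sign/symptom	morning cortisol level
cholesterol level	sign/symptom	cholesterol level
head trauma	sign/symptom	head trauma
abdominal adiposity	sign/symptom	abdominal adiposity
fracture	sign/symptom	fracture
bone mineral density	sign/symptom	bone mineral density;BMD
body mass index	sign/symptom	body mass index;BMI
pregnancy outcome	sign/symptom	pregnancy outcome
maternal influenza	sign/symptom	maternal influenza
postmenopause	sign/symptom	postmenopause
mood	sign/symptom	mood
volume of cerebrum	sign/symptom	volume of cerebrum
volume of hippocampus	sign/symptom	volume of hippocampus
volume of lateral ventricle	sign/symptom	volume of lateral ventricle
family history	sign/symptom	family history
motor activity assessment	sign/symptom	motor activity assessment
caffeine	chemical compound	caffeine
hormone	chemical compound	hormone
aflatoxin	chemical compound	aflatoxin
calcium deficiency or overdose	chemical compound	calcium deficiency;calcium overdose
phosphorus deficiency or overdose	chemical compound	phosphorus deficiency;phosphorus overdose
magnesium deficiency or overdose	chemical compound	magnesium deficiency;magnesium overdose
sodium deficiency or overdose	chemical compound	sodium deficiency;sodium overdose
potassium deficiency or overdose	chemical compound	potassium deficiency;potassium overdose
sulphur deficiency or overdose	chemical compound	sulphur deficiency;sulphur overdose
chloride deficiency or overdose	chemical compound	chloride deficiency;chloride overdose
chromium deficiency or overdose	chemical compound	chromium deficiency;chromium overdose
copper deficiency or overdose	chemical compound	copper deficiency;copper overdose
fluoride deficiency or overdose	chemical compound	fluoride deficiency;fluoride overdose
iodine deficiency or overdose	chemical compound	iodine deficiency;iodine overdose
iron deficiency or overdose	chemical compound	iron deficiency;iron overdose
manganese deficiency or overdose	chemical compound	manganese deficiency;manganese overdose
molybdenum deficiency or overdose	chemical compound	molybdenum deficiency;molybdenum overdose
selenium deficiency or overdose	chemical compound	selenium deficiency;selenium overdose
zinc deficiency or overdose	chemical compound	zinc deficiency;zinc overdose
vitamin A	chemical compound	vitamin A;retinol
vitamin B1	chemical compound	vitamin B1;thiamine
vitamin B2	chemical compound	vitamin B2;riboflavin
vitamin B3	chemical compound	vitamin B3;niacin
vitamin B5	chemical compound	vitamin B5;pantothenic acid
vitamin B6	chemical compound	vitamin B6;pyridoxine
vitamin B7	chemical compound	vitamin B7;biotin
vitamin B9	chemical compound	vitamin B9;folic acid
vitamin B12	chemical compound	vitamin B12;cyanocobalamin
vitamin C	chemical compound	vitamin C;ascorbic acid
vitamin D	chemical compound	vitamin D;calciferol
vitamin E	chemical compound	vitamin E;tocopherol
vitamin K	chemical compound	vitamin K;phylloquinone
cannabis	chemical compound	cannabis
cocaine	chemical compound	cocaine
bisphenol-A	chemical compound	bisphenol-A;BPA
diethylstilbestrol	chemical compound	diethylstilbestrol;DES
estradiol	chemical compound	estradiol;E2
oral contraceptive	chemical compound	oral contraceptive;OC
air pollutants	environmental/lifestyle	air pollutants
volatile organic compounds	environmental/lifestyle	volatile organic compounds
pesticide	environmental/lifestyle	pesticide
chemical agents	environmental/lifestyle	chemical agents
wood dust exposure	environmental/lifestyle	wood dust exposure
silica dust exposure	environmental/lifestyle	silica dust exposure
night shift work	environmental/lifestyle	night shift work
outdoor workers	environmental/lifestyle	outdoor workers
indoor workers	environmental/lifestyle	indoor workers
exposure polycyclic aromatic hydrocarbons	environmental/lifestyle	polycyclic aromatic hydrocarbons
heterosexual	environmental/lifestyle	heterosexual
homosexual	environmental/lifestyle	homosexual
tobacco smoking	environmental/lifestyle	tobacco smoking
alcohol consumption	environmental/lifestyle	alcohol consumption
health education and health promotion	environmental/lifestyle	health education;health promotion
addiction	environmental/lifestyle	addiction
lifestyle intervention	environmental/lifestyle	lifestyle intervention
diet nutrition	environmental/lifestyle	diet nutrition
stress	environmental/lifestyle	stress
age gender	environmental/lifestyle	age;gender
breast-feeding	environmental/lifestyle	breast-feeding
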