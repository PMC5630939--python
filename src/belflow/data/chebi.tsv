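id	preferred_name	synonyms	namespace
20-HETE	20-HETE	20-hydroxyeicosatetraenoic acid	CHEBI
cholesterol	cholesterol		CHEBI
oxidized LDL	oxidized LDL	ox-LDL	CHEBI
nitric oxide	nitric oxide		CHEBI
superoxide	superoxide	superoxide anion	CHEBI
hydrogen peroxide	hydrogen peroxide		CHEBI
peroxynitrite	peroxynitrite		CHEBI
angiotensin II	angiotensin II	Ang II	CHEBI
prostaglandin E2	prostaglandin E2	PGE2	CHEBI
thromboxane A2	thromboxane A2	TXA2	CHEBI
prostacyclin	prostacyclin	PGI2	CHEBI
leukotriene B4	leukotriene B4	LTB4	CHEBI
arachidonic acid	arachidonic acid		CHEBI
linoleic acid	linoleic acid		CHEBI
oleic acid	oleic acid		CHEBI
palmitic acid	palmitic acid		CHEBI
triglyceride	triglyceride	triacylglycerol	CHEBI
phosphatidylcholine	phosphatidylcholine		CHEBI
lysophosphatidylcholine	lysophosphatidylcholine	lyso-PC	CHEBI
sphingosine 1-phosphate	sphingosine 1-phosphate	S1P	CHEBI
ceramide	ceramide		CHEBI
7-ketocholesterol	7-ketocholesterol		CHEBI
homocysteine	homocysteine		CHEBI
glucose	glucose		CHEBI
insulin	insulin		CHEBI
adenosine	adenosine		CHEBI
ATP	ATP	adenosine triphosphate	CHEBI
cAMP	cAMP		CHEBI
cGMP	cGMP		CHEBI
calcium ion	calcium ion	Ca2+	CHEBI
heparin	heparin		CHEBI
warfarin	warfarin		CHEBI
aspirin	aspirin	acetylsalicylic acid	CHEBI
clopidogrel	clopidogrel		CHEBI
atorvastatin	atorvastatin		CHEBI
simvastatin	simvastatin		CHEBI
pravastatin	pravastatin		CHEBI
rosuvastatin	rosuvastatin		CHEBI
ezetimibe	ezetimibe		CHEBI
niacin	niacin	nicotinic acid	CHEBI
fenofibrate	fenofibrate		CHEBI
metformin	metformin		CHEBI
pioglitazone	pioglitazone		CHEBI
rosiglitazone	rosiglitazone		CHEBI
losartan	losartan		CHEBI
candesartan	candesartan		CHEBI
enalapril	enalapril		CHEBI
captopril	captopril		CHEBI
amlodipine	amlodipine		CHEBI
nifedipine	nifedipine		CHEBI
doxycycline	doxycycline		CHEBI
rapamycin	rapamycin	sirolimus	CHEBI
paclitaxel	paclitaxel		CHEBI
curcumin	curcumin		CHEBI
resveratrol	resveratrol		CHEBI
quercetin	quercetin		CHEBI
vitamin E	vitamin E	alpha-tocopherol	CHEBI
vitamin D3	vitamin D3	cholecalciferol	CHEBI
folic acid	folic acid	folate	CHEBI
L-arginine	L-arginine		CHEBI
L-NAME	L-NAME		CHEBI
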