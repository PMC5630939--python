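id	preferred_name	synonyms	namespace
angiogenesis	angiogenesis	microvessel density|neovascularization	GOBP
blood vessel development	blood vessel development		GOBP
vasculogenesis	vasculogenesis		GOBP
inflammatory response	inflammatory response	inflammation	GOBP
immune response	immune response		GOBP
cell adhesion	cell adhesion	leukocyte adhesion	GOBP
chemotaxis	chemotaxis	leukocyte chemotaxis	GOBP
cell migration	cell migration	monocyte migration	GOBP
cell proliferation	cell proliferation		GOBP
apoptotic process	apoptotic process	apoptosis|programmed cell death	GOBP
autophagy	autophagy		GOBP
lipid metabolic process	lipid metabolic process	lipid metabolism	GOBP
cholesterol efflux	cholesterol efflux		GOBP
cholesterol homeostasis	cholesterol homeostasis		GOBP
lipoprotein metabolic process	lipoprotein metabolic process		GOBP
foam cell differentiation	foam cell differentiation	foam cell formation	GOBP
macrophage activation	macrophage activation		GOBP
macrophage chemotaxis	macrophage chemotaxis		GOBP
platelet activation	platelet activation		GOBP
platelet aggregation	platelet aggregation		GOBP
blood coagulation	blood coagulation	coagulation	GOBP
fibrinolysis	fibrinolysis		GOBP
thrombosis	thrombosis		GOBP
hemostasis	hemostasis		GOBP
extracellular matrix disassembly	extracellular matrix disassembly	matrix degradation	GOBP
extracellular matrix organization	extracellular matrix organization	matrix remodeling	GOBP
collagen catabolic process	collagen catabolic process	collagen degradation	GOBP
collagen biosynthetic process	collagen biosynthetic process		GOBP
elastic fiber assembly	elastic fiber assembly		GOBP
wound healing	wound healing		GOBP
smooth muscle cell proliferation	smooth muscle cell proliferation		GOBP
smooth muscle cell migration	smooth muscle cell migration		GOBP
endothelial cell proliferation	endothelial cell proliferation		GOBP
endothelial cell migration	endothelial cell migration		GOBP
endothelial cell apoptotic process	endothelial cell apoptotic process	endothelial apoptosis	GOBP
vascular permeability	vascular permeability		GOBP
vasoconstriction	vasoconstriction		GOBP
vasodilation	vasodilation		GOBP
blood pressure regulation	blood pressure regulation		GOBP
nitric oxide biosynthetic process	nitric oxide biosynthetic process	nitric oxide production	GOBP
oxidative stress response	oxidative stress response	response to oxidative stress	GOBP
lipid oxidation	lipid oxidation		GOBP
low-density lipoprotein particle oxidation	low-density lipoprotein particle oxidation	LDL oxidation	GOBP
phagocytosis	phagocytosis		GOBP
efferocytosis	efferocytosis		GOBP
antigen presentation	antigen presentation		GOBP
T cell activation	T cell activation		GOBP
T cell differentiation	T cell differentiation		GOBP
B cell activation	B cell activation		GOBP
leukocyte transendothelial migration	leukocyte transendothelial migration		GOBP
monocyte differentiation	monocyte differentiation		GOBP
cytokine production	cytokine production		GOBP
interleukin-6 production	interleukin-6 production		GOBP
chemokine production	chemokine production		GOBP
acute-phase response	acute-phase response		GOBP
complement activation	complement activation		GOBP
calcification	calcification	vascular calcification	GOBP
ossification	ossification		GOBP
cell death	cell death	necrosis	GOBP
senescence	senescence	cellular senescence	GOBP
angiotensin signaling	angiotensin signaling		GOBP
lipid storage	lipid storage		GOBP
cholesterol transport	cholesterol transport		GOBP
triglyceride metabolic process	triglyceride metabolic process		GOBP
glucose homeostasis	glucose homeostasis		GOBP
insulin signaling	insulin signaling		GOBP
leukocyte rolling	leukocyte rolling		GOBP
mast cell degranulation	mast cell degranulation		GOBP
neutrophil extracellular trap formation	neutrophil extracellular trap formation	NETosis	GOBP
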