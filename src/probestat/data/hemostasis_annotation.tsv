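gene_id	accession	functional_class	function
LPP1	AB000888.1	lysophospholipid	Dephosphorylates LPA, S1P, PA, ceramide-1-P
LPP2	AF047760.1	lysophospholipid	Dephosphorylates LPA, S1P, PA, ceramide-1-P
LPP3	NM_003713	lysophospholipid	Dephosphorylates LPA, S1P, PA, ceramide-1-P
LYPLA1	AF077198.1	lysophospholipid	Hydrolyzes lysophosphatidylcholine to LPA
LYPLA2	NM_007260.1	lysophospholipid	Hydrolyzes lysophosphatidylcholine to LPA
AGPAT1	U56417	lysophospholipid	ER enzyme converting LPA to PA
AGPAT2	U56418	lysophospholipid	ER enzyme converting LPA to PA
AGPAT3	NM_020132	lysophospholipid	ER enzyme converting LPA to PA
SGPP1	NM_030791	lysophospholipid	Dephosphorylates S1P
SGPL1	NM_003901.1	lysophospholipid	Irreversible sphingosine 1-phosphate degradation
SPHK1	NM_021972.1	lysophospholipid	Phosphorylates sphingosine
EDG2	45580697	lysophospholipid	LPA receptor
EDG3	NM_005226	lysophospholipid	LPA receptor
ROCK2	D87931	lysophospholipid	LPA activated kinase
F7	NM_000131.2	coagulant	Activates the coagulation cascade by converting factor X to factor Xa
F8	NM_000132.2	coagulant	Intrinsic pathway of blood coagulation
VWF	NM_000552.2	coagulant	Bridge between platelet glycoprotein GPIb/IX and collagen
VKORC1	NM_024006	coagulant	Required for carboxylation of glutamic acid residues in clotting proteins
GGCX	BE326952	coagulant	Carboxylation of coagulation factors
F13A1	NM_000129.2	coagulant	Last zymogen activated in the coagulation cascade
THBD	AF022742	anti-coagulant	Binds thrombin, activates protein C, degrades factors Va and VIIIa
PROS1	NM_000313	anti-coagulant	Cofactor to anticoagulant activated protein C
PROCR	34335271	anti-coagulant	Membrane protein enhancing activation of protein C
TFPI	J03225.1	anti-coagulant	Inhibits tissue factor
ANXA5	NM_001154	anti-coagulant	Protective shield over thrombogenic cell surfaces
PAFAH1B1	NM_000430.2	anti-coagulant	Removes the SN-2 acetyl group of platelet-activating factor
ANXA2	NM_004039	fibrinolytic	Profibrinolytic co-receptor for tPA and plasminogen
PLAT	NM_000930	fibrinolytic	Conversion of plasminogen to plasmin (tissue-type)
PLAU	NM_002658	fibrinolytic	Conversion of plasminogen to plasmin (urokinase-type)
PLAUR	X74039.1	fibrinolytic	Binds uPA and permits activation of pro-enzyme by plasmin
CLEC3B	NM_003278	fibrinolytic	Tetranectin; binds fibrin and coactivates plasminogen
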