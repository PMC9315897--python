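# Representative antidepressant lexicon (synthetic stand-in for a full
# drug vocabulary): 35 active substances with 82 Spanish-market brand names.
# Brand rows carry the substance concept_id; canonical is the substance INN.
surface	language	category	concept_id	canonical
citalopram	both	drug_substance	N06AB04	citalopram
escitalopram	both	drug_substance	N06AB10	escitalopram
fluoxetina	both	drug_substance	N06AB03	fluoxetina
fluvoxamina	both	drug_substance	N06AB08	fluvoxamina
paroxetina	both	drug_substance	N06AB05	paroxetina
sertralina	both	drug_substance	N06AB06	sertralina
venlafaxina	both	drug_substance	N06AX16	venlafaxina
desvenlafaxina	both	drug_substance	N06AX23	desvenlafaxina
duloxetina	both	drug_substance	N06AX21	duloxetina
reboxetina	both	drug_substance	N06AX18	reboxetina
mirtazapina	both	drug_substance	N06AX11	mirtazapina
mianserina	both	drug_substance	N06AX03	mianserina
trazodona	both	drug_substance	N06AX05	trazodona
bupropion	both	drug_substance	N06AX12	bupropion
agomelatina	both	drug_substance	N06AX22	agomelatina
vortioxetina	both	drug_substance	N06AX26	vortioxetina
tianeptina	both	drug_substance	N06AX14	tianeptina
amitriptilina	both	drug_substance	N06AA09	amitriptilina
nortriptilina	both	drug_substance	N06AA10	nortriptilina
clomipramina	both	drug_substance	N06AA04	clomipramina
imipramina	both	drug_substance	N06AA02	imipramina
trimipramina	both	drug_substance	N06AA06	trimipramina
doxepina	both	drug_substance	N06AA12	doxepina
maprotilina	both	drug_substance	N06AA21	maprotilina
amoxapina	both	drug_substance	N06AA17	amoxapina
lofepramina	both	drug_substance	N06AA07	lofepramina
dosulepina	both	drug_substance	N06AA16	dosulepina
protriptilina	both	drug_substance	N06AA11	protriptilina
moclobemida	both	drug_substance	N06AG02	moclobemida
tranilcipromina	both	drug_substance	N06AF04	tranilcipromina
fenelzina	both	drug_substance	N06AF03	fenelzina
isocarboxazida	both	drug_substance	N06AF01	isocarboxazida
nefazodona	both	drug_substance	N06AX06	nefazodona
milnacipran	both	drug_substance	N06AX17	milnacipran
oxitriptan	both	drug_substance	N06AX01	oxitriptan
Seropram	both	drug_brand	N06AB04	citalopram
Prisdal	both	drug_brand	N06AB04	citalopram
Celexa	both	drug_brand	N06AB04	citalopram
Cipralex	both	drug_brand	N06AB10	escitalopram
Esertia	both	drug_brand	N06AB10	escitalopram
Heipram	both	drug_brand	N06AB10	escitalopram
Lexapro	both	drug_brand	N06AB10	escitalopram
Prozac	both	drug_brand	N06AB03	fluoxetina
Adofen	both	drug_brand	N06AB03	fluoxetina
Reneuron	both	drug_brand	N06AB03	fluoxetina
Lecimar	both	drug_brand	N06AB03	fluoxetina
Dumirox	both	drug_brand	N06AB08	fluvoxamina
Luvox	both	drug_brand	N06AB08	fluvoxamina
Seroxat	both	drug_brand	N06AB05	paroxetina
Frosinor	both	drug_brand	N06AB05	paroxetina
Motivan	both	drug_brand	N06AB05	paroxetina
Daparox	both	drug_brand	N06AB05	paroxetina
Casbol	both	drug_brand	N06AB05	paroxetina
Besitran	both	drug_brand	N06AB06	sertralina
Aremis	both	drug_brand	N06AB06	sertralina
Altisben	both	drug_brand	N06AB06	sertralina
Vandral	both	drug_brand	N06AX16	venlafaxina
Dobupal	both	drug_brand	N06AX16	venlafaxina
Zarelis	both	drug_brand	N06AX16	venlafaxina
Flaxen	both	drug_brand	N06AX16	venlafaxina
Pristiq	both	drug_brand	N06AX23	desvenlafaxina
Khedezla	both	drug_brand	N06AX23	desvenlafaxina
Cymbalta	both	drug_brand	N06AX21	duloxetina
Xeristar	both	drug_brand	N06AX21	duloxetina
Ariclaim	both	drug_brand	N06AX21	duloxetina
Yentreve	both	drug_brand	N06AX21	duloxetina
Irenor	both	drug_brand	N06AX18	reboxetina
Norebox	both	drug_brand	N06AX18	reboxetina
Rexer	both	drug_brand	N06AX11	mirtazapina
Vastat	both	drug_brand	N06AX11	mirtazapina
Remeron	both	drug_brand	N06AX11	mirtazapina
Lantanon	both	drug_brand	N06AX03	mianserina
Tolvon	both	drug_brand	N06AX03	mianserina
Deprax	both	drug_brand	N06AX05	trazodona
Desyrel	both	drug_brand	N06AX05	trazodona
Elontril	both	drug_brand	N06AX12	bupropion
Zyntabac	both	drug_brand	N06AX12	bupropion
Wellbutrin	both	drug_brand	N06AX12	bupropion
Valdoxan	both	drug_brand	N06AX22	agomelatina
Thymanax	both	drug_brand	N06AX22	agomelatina
Brintellix	both	drug_brand	N06AX26	vortioxetina
Trintellix	both	drug_brand	N06AX26	vortioxetina
Stablon	both	drug_brand	N06AX14	tianeptina
Tryptizol	both	drug_brand	N06AA09	amitriptilina
Deprelio	both	drug_brand	N06AA09	amitriptilina
Elavil	both	drug_brand	N06AA09	amitriptilina
Paxtibi	both	drug_brand	N06AA10	nortriptilina
Norfenazin	both	drug_brand	N06AA10	nortriptilina
Pamelor	both	drug_brand	N06AA10	nortriptilina
Anafranil	both	drug_brand	N06AA04	clomipramina
Clofranil	both	drug_brand	N06AA04	clomipramina
Tofranil	both	drug_brand	N06AA02	imipramina
Janimine	both	drug_brand	N06AA02	imipramina
Surmontil	both	drug_brand	N06AA06	trimipramina
Sinequan	both	drug_brand	N06AA12	doxepina
Silenor	both	drug_brand	N06AA12	doxepina
Ludiomil	both	drug_brand	N06AA21	maprotilina
Deprilept	both	drug_brand	N06AA21	maprotilina
Demolox	both	drug_brand	N06AA17	amoxapina
Asendin	both	drug_brand	N06AA17	amoxapina
Deftan	both	drug_brand	N06AA07	lofepramina
Gamanil	both	drug_brand	N06AA07	lofepramina
Prothiaden	both	drug_brand	N06AA16	dosulepina
Dothep	both	drug_brand	N06AA16	dosulepina
Vivactil	both	drug_brand	N06AA11	protriptilina
Concordin	both	drug_brand	N06AA11	protriptilina
Manerix	both	drug_brand	N06AG02	moclobemida
Parnate	both	drug_brand	N06AF04	tranilcipromina
Nardelzine	both	drug_brand	N06AF03	fenelzina
Nardil	both	drug_brand	N06AF03	fenelzina
Marplan	both	drug_brand	N06AF01	isocarboxazida
Dutonin	both	drug_brand	N06AX06	nefazodona
Rulivan	both	drug_brand	N06AX06	nefazodona
Ixel	both	drug_brand	N06AX17	milnacipran
Savella	both	drug_brand	N06AX17	milnacipran
Telesol	both	drug_brand	N06AX01	oxitriptan
Cincofarm	both	drug_brand	N06AX01	oxitriptan
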