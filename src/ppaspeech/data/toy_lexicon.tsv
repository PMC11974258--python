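lemma	per_million
cane	120.0
parco	50.0
bambina	80.0
bambino	95.0
uomo	310.0
donna	220.0
albero	15.5
casa	480.0
tavolo	60.0
sedia	28.0
libro	140.0
acqua	260.0
cestino	6.5
coperta	12.0
aquilone	2.5
barca	35.0
lago	22.0
pesce	35.0
canna	8.0
radio	35.0
musica	110.0
panino	9.0
bottiglia	25.0
bicchiere	30.0
cappello	18.0
scarpa	20.0
erba	14.0
fiore	40.0
sole	90.0
cielo	75.0
nuvola	10.0
sabbia	11.0
giornale	45.0
occhiale	16.0
mano	330.0
piede	70.0
testa	180.0
famiglia	270.0
signora	130.0
signore	150.0
ragazzo	160.0
ragazza	140.0
gioco	85.0
palla	26.0
picnic	3.0
prato	13.0
bandiera	9.5
macchina	150.0
strada	190.0
gente	230.0
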