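taking	take
running	run
daily	daili
rational	ration
oxycontin	oxycontin
percocet	percocet
abusing	abus
abused	abus
abuser	abus
addiction	addict
addicted	addict
addictive	addict
relational	relat
conditional	condit
agreement	agreement
replacement	replac
adjustment	adjust
dependent	depend
adoption	adopt
adopted	adopt
communism	commun
activate	activ
angulate	angul
probate	probat
conflated	conflat
troubling	troubl
vileness	vile
hopefulness	hope
callousness	callous
formality	formal
sensitivity	sensit
sensibility	sensibl
triplicate	triplic
formative	form
formalize	formal
electricity	electr
electrical	electr
hopeful	hope
goodness	good
generalization	gener
generalizations	gener
predication	predic
operator	oper
feudalism	feudal
decisiveness	decis
sensitiveness	sensit
homologous	homolog
analogously	analog
effective	effect
allowance	allow
inference	infer
airliner	airlin
gyroscopic	gyroscop
adjustable	adjust
defensible	defens
irritant	irrit
replication	replic
bowdlerize	bowdler
cement	cement
dissolve	dissolv
happy	happi
sky	sky
crying	cry
flying	fly
dying	dy
lying	ly
tying	ty
trying	try
visualization	visual
visualize	visual
organization	organ
organized	organ
medication	medic
medicated	medic
prescriptions	prescript
prescription	prescript
prescribed	prescrib
tablets	tablet
capsules	capsul
injection	inject
injections	inject
snorting	snort
smoking	smoke
drinking	drink
popped	pop
crushed	crush
swallowed	swallow
grinding	grind
milligrams	milligram
dosage	dosag
doses	dose
overdose	overdos
overdosing	overdos
withdrawal	withdraw
withdrawals	withdraw
craving	crave
cravings	crave
relapse	relaps
relapsed	relaps
relapsing	relaps
sober	sober
sobriety	sobrieti
recovery	recoveri
recovering	recov
rehabilitation	rehabilit
detoxification	detoxif
tolerance	toler
tolerant	toler
dependence	depend
painkillers	painkil
painkiller	painkil
relievers	reliev
suboxone	suboxon
methadone	methadon
naloxone	naloxon
fentanyl	fentanyl
oxycodone	oxycodon
hydrocodone	hydrocodon
tramadol	tramadol
morphine	morphin
codeine	codein
heroin	heroin
opioids	opioid
opiates	opiat
narcotics	narcot
pharmaceutical	pharmaceut
pharmacies	pharmaci
epidemic	epidem
epidemics	epidem
surveillance	surveil
monitoring	monitor
classified	classifi
classifier	classifi
classifiers	classifi
classification	classif
ensemble	ensembl
voting	vote
sampling	sampl
resampling	resampl
validation	valid
testing	test
trained	train
training	train
learner	learner
learning	learn
embedding	embed
embeddings	embed
tokenization	token
stemmed	stem
stemming	stem
correlated	correl
correlation	correl
correlations	correl
significance	signific
statistically	statist
annotated	annot
annotation	annot
annotators	annot
agreeable	agreeabl
feed	feed
agreed	agre
plastered	plaster
singing	sing
singer	singer
sings	sing
conflation	conflat
controllable	control
rolling	roll
roll	roll
meetings	meet
meeting	meet
siezed	siez
sized	size
hopping	hop
hopped	hop
hoping	hope
hoped	hope
tanned	tan
fizzed	fizz
failing	fail
filing	file
caresses	caress
ponies	poni
ties	ti
caress	caress
cats	cat
feet	feet
matting	mat
mating	mate
meting	mete
messing	mess
motoring	motor
motored	motor
generalizing	gener
probabilistic	probabilist
likelihood	likelihood
frequencies	frequenc
proportions	proport
populations	popul
counties	counti
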