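gene	flybase_id	function	bias_label
Act5C	FBgn0000042	cytoskeleton structure	unbiased
Ance	FBgn0012037	peptidase	unbiased
aux	FBgn0037218	ATP binding cofactor of kinase	unbiased
blanks	FBgn0035608	siRNA binding	male_biased
Bug22	FBgn0032248	cilium organization and assembly	unbiased
CdsA	FBgn0010350	enzyme (CDP diglyceride synthetase)	unbiased
Chc	FBgn0000319	coated vesicles structure	unbiased
ctp	FBgn0011760	dynein complex assembly	unbiased
Cul3	FBgn0261268	protein binding	unbiased
Cyt-c-d	FBgn0086907	electron carrier	male_biased
Dark	FBgn0263864	apoptosome assembly	unbiased
didum	FBgn0261397	unconventional myosin	unbiased
Dredd	FBgn0020381	enzyme (caspase)	unbiased
Dronc	FBgn0026404	enzyme (caspase)	unbiased
Duba	FBgn0036180	enzyme (deubiquitinase)	unbiased
EcR	FBgn0000546	transcription factor	unbiased
eIF3m	FBgn0033902	translation initiation factor	unbiased
Fadd	FBgn0038928	protein binding	unbiased
gish	FBgn0250823	enzyme (protein kinase)	unbiased
gudu	FBgn0031905	NA	male_biased
heph	FBgn0011224	mRNA binding (translation repression)	unbiased
hmw	FBgn0038607	motile cilium assembly	male_biased
jar	FBgn0011225	myosin	unbiased
klhl10	FBgn0040038	substrate recruiting for ubiquitin ligase complex	male_biased
Lasp	FBgn0063485	actin/myosin scaffolding	unbiased
Mer	FBgn0086384	cytoskeletal protein binding	unbiased
mlt	FBgn0265512	microtubule removal	unbiased
nes	FBgn0026630	enzyme (lysophospholipid acyltransferase)	unbiased
Npc1a	FBgn0024320	sterol metabolism	unbiased
nsr	FBgn0034740	dynein complex assembly	male_biased
orb2	FBgn0264307	translation factor	unbiased
Osbp	FBgn0020626	protein binding	unbiased
oys	FBgn0033476	enzyme (lysophospholipid acyltransferase)	unbiased
Past1	FBgn0016693	membrane assembly	unbiased
Pen	FBgn0011823	protein binding	unbiased
poe	FBgn0011230	calmodulin binding	unbiased
porin	FBgn0004363	membrane channel protein	unbiased
Prosalpha6T	FBgn0032492	enzyme (protease)	male_biased
scat	FBgn0011232	protein binding	female_biased
shi	FBgn0003392	GTPase for microtubule motility	unbiased
skap	FBgn0037643	ATP binding enzyme	unbiased
sw	FBgn0003654	dynein complex assembly	unbiased
Taz	FBgn0026619	enzyme (phospholipid transacylase)	unbiased
Vps28	FBgn0021814	vesicular trafficking	unbiased
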