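family	up	sequence	down	amidated
Chromogranin-A	EKR	LEGEDDPDRSMKLSFRARAYGFRDPGPQL	RRG	false
Chromogranin-A	NRR	AEDQELESLSAIEAELEKVAHQLQALRR	G	true
Cocaine- and amphetamine-regulated transcript protein	PRR	QLRAPGAVLQIEALQEVLKKLKS	KRI	false
Corticotropin-releasing hormone	AER	GAEDALGGHQ	GAL	true
Galanin	EKR	GWTLNSAGYLLGPHAIDNHRSFSDKHGLTG	KRE	false
Galanin	GKR	ELPLEVEEGRL	GSV	true
Glucagon	DKR	HSQGTFTSDYSKYLDS	RRA	false
Glucagon	GRR	DFPEEVAIAEEL	GRR	true
Kisspeptin-1	VQR	EKDMSAYNWNSFGLRY	GRR	true
Neuropeptide S	MKR	SFRNGVGSGVKKTSF	RRA	false
Neurosecretory protein VGF	ATR	QAAAQEERLADLASDLLLQYLLQGGARQRDLG	GRG	true
Neurosecretory protein VGF	VRR	LEGSFLGGSEAGERLLQQGLAQVEAG	RRQ	false
Nucleobindin-2	EKR	KEEEAKFAEM	KRK	false
Pituitary adenylate cyclase-activating polypeptide	TKR	HSDGIFTDSYSRY	RKQ	false
Pituitary adenylate cyclase-activating polypeptide	YRK	QMAVKKYLAAVL	GKR	true
Proenkephalin-A	MKK	DADEGDTLANSSDLLKELLGTGDNRAKDSHQQESTNNDEDSTSKRYGGFMRGL	KRS	false
Proenkephalin-A	MKR	YGGFMKKMDELYPVEPEEEANGGEILAKRYGGFM	KKD	false
Proenkephalin-A	QKR	YGGFMRRV	GRP	true
Proenkephalin-A	QKR	YGGFMRRVGRPEWWMDYQKRYGGFL	KRF	false
Pro-FMRFamide-related neuropeptide FF	FGR	NAWGPWSKEQLSPQAREFWSLAAPQRF	GKK	true
Pro-FMRFamide-related neuropeptide VF	SPR	ARANMEAGTMSHFPSLPQRF	GRT	true
Progonadoliberin-1	DLR	GALERLIEEEA	GQK	true
Prohormone convertase 2	HKR	QLERDPRIKMALQQEGFD	RKK	false
Prohormone convertase 2	SKR	NQLHDEVHQW	RRN	false
Pro-opiomelanocortin	FKR	ELEGEQPDGLEHVLEPDTEKADGPYRVEHFRWGNPPKD	KRY	false
Pro-opiomelanocortin	GKK	RRPVKVYPNVAENESAEAFPLEF	KRE	false
Pro-opiomelanocortin	GKR	SYSMEHFRWGKPVGKK	RRP	false
ProSAAS	LRR	AVDQDLGPEVPPENVL	GAL	true
Protachykinin-1	GKR	DAGHGQISHKMAYERSAMQNYE	RRR	false
Protachykinin-1	GKR	DAGHGQISHKRHKTDSFVGLM	GKR	true
Protachykinin-1	HKR	HKTDSFVGLMG	KRA	false
Pro-thyrotropin-releasing hormone	ERR	FLWKDLQRVR	GDL	true
Pro-thyrotropin-releasing hormone	GKR	EEEEKDIEAEER	GDL	true
Pro-thyrotropin-releasing hormone	GKR	EEEEKDIEAEERGDLGEGGAWRLH	KRQ	false
Pro-thyrotropin-releasing hormone	TKR	QHPGRRFIDPELQRSWEEKEGEGVLMPE	KRQ	false
Pro-thyrotropin-releasing hormone	VKR	QHPGRRSFPWMESDVT	KRQ	false
Secretogranin-1	EKR	KRLGALFNPYFDPLQWKNSDFE	KKG	false
Secretogranin-1	EKR	PFSEDVNW	GYE	true
Secretogranin-1	EKR	SFARAPHLDL	KRQ	false
Secretogranin-1	LRK	SGKEVKGEEKGENENSKFEVRLLRDPSDASV	GRW	true
Secretogranin-1	NKR	SEASAKKKEESVARAEAHFVELEKTHSREQSSQESGEET	RRQ	false
Secretogranin-1	TRR	QEKPQELPDQDQSEEESEEGEEGEEGATSEVT	KRR	false
Secretogranin-1	YKR	NHPDSELESTANRHSEETEEERSYEGAKGRQHRGRGREPGAYPALDSRQE	KRL	false
Secretogranin-2	LKR	VPSPGSSEDDLQEEEQLEQAIKEHL	GQG	true
Secretogranin-2	LKR	VPSPGSSEDDLQEEEQLEQAIKEHLGQGSSQEMEKLAKVS	KRI	false
Secretogranin-2	MKR	SGHLGLPDE	GNR	true
Secretogranin-2	SKR	IPAGSLKNEDTPNRQYLDEDMLLKVLEYLNQEQAEQ	GRE	true
Secretogranin-2	SKR	IPAGSLKNEDTPNRQYLDEDMLLKVLEYLNQEQAEQGREHLA	KRA	false
Secretogranin-5	RKR	RSVNPYLQ	GKR	true
Tachykinin-3	QKR	DMHDFFVGLMG	KRN	false
Urocortin 3	SKK	NFGYLPTQDPSGEEEDEQKHIKN	KRT	false
Urocortin 3	VKK	NKLEDVPVLS	KKN	false
VIP peptides	GKR	ISSSISEDPVPV	KRH	false
VIP peptides	LRK	QMAVKKYLNSILN	GKR	true
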