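# Fixture sentiment mini-lexicon (synthetic; SentiWordNet-3.0 file layout, not SentiWordNet data).
# POS	ID	PosScore	NegScore	SynsetTerms	Gloss
a	00000001	0.875	0	happy#1	feeling or showing pleasure
a	00000002	0.625	0.125	happy#2	marked by good fortune
a	00000003	0.75	0	glad#1	showing or causing joy
a	00000004	0.875	0	joyful#1	full of high-spirited delight
a	00000005	0.75	0	hopeful#1	having or manifesting hope
a	00000006	0.625	0	grateful#1	feeling or showing gratitude
a	00000007	0.75	0	thankful#1	feeling or showing gratitude
a	00000008	0.625	0.125	relieved#1	free from worry
a	00000009	0.875	0	wonderful#1	extraordinarily good
a	00000010	0.75	0	amazing#1	inspiring awe or admiration
a	00000011	0.625	0	supportive#1	furnishing support or assistance
a	00000012	0.75	0	loving#1	feeling or showing love
a	00000013	0.625	0	encouraging#1	giving courage or confidence
a	00000014	0.875	0	blessed#1	highly favored or fortunate
a	00000015	0.75	0	brave#1	possessing or displaying courage
a	00000016	0.625	0	strong#2	of good quality and condition
a	00000017	0.75	0	proud#1	feeling self-respect or pleasure
a	00000018	0.625	0	inspiring#1	stimulating or exalting to the spirit
a	00000019	0.875	0	beautiful#1	delighting the senses
a	00000020	0.625	0	kind#1	having a tender nature
a	00000021	0.75	0	caring#1	feeling and exhibiting concern
a	00000022	0.625	0	gentle#2	having a kindly disposition
a	00000023	0.75	0	cheerful#1	being full of good spirits
a	00000024	0.625	0	comforting#1	providing freedom from worry
a	00000025	0.75	0	uplifting#1	exalting in spirit
n	00000026	0.625	0	blessing#1	a desirable state
n	00000027	0.75	0	courage#1	a quality of spirit
n	00000028	0.625	0	hope#2	the general feeling that some desire will be fulfilled
n	00000029	0.625	0	comfort#1	a state of being relaxed
n	00000030	0.75	0	love#1	a strong positive emotion
v	00000031	0.625	0	cherish#1	be fond of
v	00000032	0.625	0	comfort#2 console#1	give moral or emotional strength to
r	00000033	0.625	0	gladly#1	in a willing manner
a	00000034	0	0.875	sad#1	experiencing sorrow or unhappiness
a	00000035	0.125	0.625	sad#2	bad or unfortunate
a	00000036	0	0.875	terrible#1	causing fear or dread
a	00000037	0	0.75	awful#1	exceptionally bad or displeasing
a	00000038	0	0.875	horrible#1	provoking horror
a	00000039	0	0.75	scared#1	made afraid
a	00000040	0	0.625	afraid#1	filled with fear or apprehension
a	00000041	0	0.75	anxious#1	causing or fraught with anxiety
a	00000042	0	0.625	worried#1	afflicted with or marked by anxious uneasiness
a	00000043	0	0.75	depressed#1	low in spirits
a	00000044	0	0.625	lonely#1	marked by dejection from being alone
a	00000045	0	0.75	hopeless#1	without hope
a	00000046	0	0.625	exhausted#1	drained of energy
a	00000047	0	0.75	miserable#1	very unhappy
a	00000048	0	0.625	painful#1	causing physical or psychological pain
a	00000049	0	0.75	devastating#1	wreaking or capable of wreaking complete destruction
a	00000050	0	0.625	frustrating#1	discouraging by hindering
a	00000051	0	0.75	frightening#1	causing fear or dread
a	00000052	0	0.625	upset#1	afflicted with or marked by distress
a	00000053	0	0.75	angry#1	feeling or showing anger
a	00000054	0	0.625	bitter#2	marked by strong resentment
a	00000055	0	0.875	dreadful#1	causing fear or dread
a	00000056	0	0.625	heartbreaking#1	causing or marked by grief
a	00000057	0	0.75	overwhelming#2	very intense and hard to bear
a	00000058	0	0.625	stressful#1	extremely irritating to the nerves
a	00000059	0	0.75	grim#1	harshly uninviting or formidable
a	00000060	0	0.625	tearful#1	filled with or marked by tears
n	00000061	0	0.75	grief#1	intense sorrow
n	00000062	0	0.625	fear#1	an emotion experienced in anticipation of pain
n	00000063	0	0.625	worry#1	something or someone that causes anxiety
n	00000064	0	0.75	despair#1	a state in which all hope is lost
n	00000065	0	0.625	sorrow#1	an emotion of great sadness
v	00000066	0	0.625	suffer#1	undergo or be subjected to
v	00000067	0	0.625	cry#2	shed tears because of sadness
r	00000068	0	0.625	sadly#1	in an unfortunate way
a	00000069	0.5	0.125	optimistic#1	expecting the best
a	00000070	0.375	0.25	emotional#1	determined or actuated by emotion
a	00000071	0.25	0.375	nervous#2	causing or fraught with apprehension
a	00000072	0.375	0.375	intense#1	in an extreme degree
a	00000073	0.5	0.25	touching#1	arousing affect
a	00000074	0.25	0.25	mixed#2	involving or composed of different elements
a	00000075	0.25	0	calm#1	not agitated
a	00000076	0	0.25	tired#1	depleted of strength or energy
a	00000077	0.25	0	fine#1	being satisfactory or in satisfactory condition
a	00000078	0.125	0.125	quiet#1	characterized by an absence of agitation
a	00000079	0	0.125	slow#1	not moving quickly
a	00000080	0.125	0	steady#1	not subject to change
n	00000081	0	0	hospital#1	a health facility where patients receive treatment
n	00000082	0	0	doctor#1	a licensed medical practitioner
n	00000083	0	0	nurse#1	one skilled in caring for the sick
n	00000084	0	0	appointment#1	a meeting arranged in advance
n	00000085	0	0	medicine#2	something that treats or prevents disease
n	00000086	0	0	morning#1	the time period between dawn and noon
n	00000087	0	0	week#1	a period of seven consecutive days
n	00000088	0	0	result#1	a phenomenon that follows a prior phenomenon
n	00000089	0	0	family#1	a social unit living together
n	00000090	0	0	treatment#1	care provided to improve a situation
n	00000091	0.125	0	recovery#1	return to an original state
n	00000092	0	0.125	diagnosis#1	identifying the nature of a disease
n	00000093	0	0	water#1	a clear liquid essential for life
n	00000094	0	0	exercise#1	the activity of exerting muscles
n	00000095	0	0	sleep#1	a natural periodic state of rest
v	00000096	0	0	walk#1	use one's feet to advance
v	00000097	0	0	eat#1	take in solid food
v	00000098	0.125	0	help#1	give assistance
v	00000099	0	0	wait#1	stay in one place in anticipation of something
a	00000100	0	0	daily#1	of or belonging to each day
a	00000101	0.25	0.25	strange#1	unusual or out of the ordinary
a	00000102	0.375	0.125	warm#2	psychologically warm and friendly
n	00000103	0.25	0.125	surprise#1	a sudden unexpected event
v	00000104	0.375	0.25	miss#3	feel or suffer from the lack of
a	00000105	0.125	0.375	hard#2	characterized by effort to the point of exhaustion
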