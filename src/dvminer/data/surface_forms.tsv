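surface	node_code	entry_kind	variants
mental health issues	F99	generic_illness	mental health issue|mental health problems|mental health concerns|mh issues
mental illness	F99	generic_illness	mental illnesses|mentally ill|mental health condition
severe mental disorder	F99	generic_illness	mental disorder|severe mental illness
unspecified mental disorder	F99	generic_illness	undiagnosed mental condition
psychiatric issues	F99	generic_illness	psych issues|psychiatric problems|psychiatric history
mood disorder	F30-39	illness	mood swings disorder|affective disorder
depression	F32	illness	depresion|depressd|major depression|clinical depression
major depressive disorder	F32	illness	mdd|major depressive episode
postpartum depression	F32.9	illness	postnatal depression|post natal depression|post-natal depression
bipolar disorder	F31.9	illness	bipolar|bi-polar|bipolar affective disorder|bipola disorder
cyclothymic disorder	F34.0	illness	cyclothymia
dysthymia	F34	illness	persistent mood disorder|persistent depressive disorder
alcohol abuse	F10	illness	alcoholism|alcoholic|alcohol dependence|alcohol addiction|alcohol problem
cannabis abuse	F12	illness	cannabis dependence|cannabis addiction|marijuana abuse|cannabis problem
amphetamine abuse	F15	illness	methamphetamine abuse|ice addiction|meth addiction|stimulant abuse
polysubstance abuse	F19	illness	polydrug abuse|poly substance abuse
substance abuse	X-SUBSTANCE-ABUSE	illness	drug abuse|drug addiction|drug dependency|substance misuse|drug habit
drug induced psychosis	X-DRUG-INDUCED	illness	drug-induced psychosis|drug induced disorder|drug-induced mental disorder
prescription drug abuse	X-DRUG-RX-ABUSE	illness	prescription medication abuse|abuse of prescription drugs
schizophrenia	F20.9	illness	schizophrenic|scitzophrenia|schizophenia|skitzophrenia|shizophrenia
paranoid schizophrenia	F20.0	illness	paranoid scitzophrenia|paranoid schizophenia
schizoaffective disorder	F25	illness	schizo-affective disorder|schizoaffective
psychosis	F29	illness	psychotic episode|psychotic illness|unspecified psychosis
anxiety	F41.9	illness	anxiety disorder|severe anxiety|anxiety issues|anxeity
panic disorder	F41.0	illness	panic attacks|panic attack
obsessive compulsive disorder	F42.9	illness	ocd|obsessive-compulsive disorder|obsessive compulsive disorde
acute stress reaction	F43.0	illness	acute stress disorder
post-traumatic stress disorder	F43.1	illness	ptsd|post traumatic stress disorder|posttraumatic stress disorder|post traumatic stress
adjustment disorder	F43	illness	adjustment issues
dissociative identity disorder	F44.81	illness	multiple personality disorder|split personality
self harm	X71-83	illness	self-harm|self harming|self-harming|selfharm|deliberate self harm
suicide attempt	T14.91	illness	attempted suicide|suicide attempts|previous suicide attempt
suicidal ideation	R45.85	illness	suicidal ideations|suicidal thoughts|suicidal
attention deficit hyperactivity disorder	F90	illness	adhd|attention deficit disorder|a.d.h.d
conduct disorder	F91	illness	conduct disorders|conduct issues
unspecified conduct disorder	F91.9	illness	conduct disorder nos
oppositional defiant disorder	F91.3	illness	oppositional defiance disorder|oppositional defient disorder
behavioural disorder	F98.9	illness	behavioral disorder|behavioural and emotional disorder|emotional and behavioural disorder
behavioural problems	F90-99	illness	behavioral problems|behavioural issues|behavioral issues
autism	F84.0	illness	autistic|autism spectrum disorder|asd
asperger syndrome	F84.5	illness	aspergers|asperger's|asperger's syndrome|aspergers syndrome|asperger
pervasive developmental disorder	F84	illness	developmental disorder|developmental delay
intermittent explosive disorder	F63.81	illness	explosive disorder
intellectual disability	F79	illness	intellectually disabled|intellectual impairment|mental retardation
mild intellectual disability	F70	illness	intellectual disability mild
personality disorder	F60.9	illness	personality disorders
borderline personality disorder	F60.3	illness	bpd|borderline pd|emotionally unstable personality disorder
paranoid personality disorder	F60.0	illness	paranoid pd
dementia	F03	illness	demensia|dimentia|dementure
alzheimer disease	G30.9	illness	alzheimer's|alzheimers|alzheimer's disease|alzheimers disease|alzheimer
down syndrome	Q90.9	illness	down's syndrome|downs syndrome|trisomy 21
huntington disease	G10-14	illness	huntington's disease|huntingtons disease|huntington's chorea
epilepsy	G00-99	illness	epileptic|seizure disorder
traumatic brain injury	X-TBI	illness	brain injury|head injury|tbi|acquired brain injury|brain damage
anger issues	R45	illness	anger management issues|anger problems
memory loss	R40-46	illness	severe memory loss
eating disorder	F50	illness	anorexia|anorexia nervosa|bulimia|bulimia nervosa
insomnia	F50-59	illness	chronic insomnia|sleep disorder
organic brain syndrome	F01-09	illness	organic brain disorder
antidepressants	MED-ANTIDEPRESSANT	medication_class	antidepressant|anti-depressants|anti-depressant|antidepressant medication
antipsychotics	MED-ANTIPSYCHOTIC	medication_class	antipsychotic|anti-psychotics|anti-psychotic|antipsychotic medication
antianxiety medication	MED-ANTIANXIETY	medication_class	anti-anxiety medication|anxiety medication|anxiolytics|antianxiety medications
neuroleptics	MED-NEUROLEPTIC	medication_class	neuroleptic|neuroleptic medication
valium	MED-ANTIANXIETY	medication_brand	diazepam
xanax	MED-ANTIANXIETY	medication_brand	alprazolam|zanax
temazepam	MED-ANTIANXIETY	medication_brand	normison|temaze
ativan	MED-ANTIANXIETY	medication_brand	lorazepam
serepax	MED-ANTIANXIETY	medication_brand	oxazepam
mogadon	MED-ANTIANXIETY	medication_brand	nitrazepam
zoloft	MED-ANTIDEPRESSANT	medication_brand	sertraline|zolof
prozac	MED-ANTIDEPRESSANT	medication_brand	fluoxetine|prozak
lexapro	MED-ANTIDEPRESSANT	medication_brand	escitalopram
cipramil	MED-ANTIDEPRESSANT	medication_brand	citalopram|celexa
effexor	MED-ANTIDEPRESSANT	medication_brand	venlafaxine
cymbalta	MED-ANTIDEPRESSANT	medication_brand	duloxetine
endep	MED-ANTIDEPRESSANT	medication_brand	amitriptyline
avanza	MED-ANTIDEPRESSANT	medication_brand	mirtazapine
aropax	MED-ANTIDEPRESSANT	medication_brand	paroxetine|paxil
seroquel	MED-ANTIPSYCHOTIC	medication_brand	quetiapine|seraquel
zyprexa	MED-ANTIPSYCHOTIC	medication_brand	olanzapine
risperdal	MED-ANTIPSYCHOTIC	medication_brand	risperidone
abilify	MED-ANTIPSYCHOTIC	medication_brand	aripiprazole
clozaril	MED-ANTIPSYCHOTIC	medication_brand	clozapine|clopine
haldol	MED-NEUROLEPTIC	medication_brand	haloperidol
largactil	MED-NEUROLEPTIC	medication_brand	chlorpromazine
modecate	MED-NEUROLEPTIC	medication_brand	fluphenazine
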