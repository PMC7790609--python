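code	label	level	parent	custom
F99	Unspecified mental disorder	1		false
F30-39	Mood (affective) disorders	1		false
F90-99	Behavioural and emotional disorders with onset usually occurring in childhood and adolescence	1		false
F10-19	Mental and behavioural disorders due to psychoactive substance use	1		false
F20-29	Schizophrenia, schizotypal, delusional, and other non-mood psychotic disorders	1		false
F40-49	Anxiety, dissociative, stress-related, somatoform, and other nonpsychotic mental disorders	1		false
X71-83	Intentional self-harm	1		false
F80-89	Pervasive and specific developmental disorders	1		false
F70-79	Intellectual disability	1		false
F60-69	Disorders of adult personality and behaviour	1		false
T08-T14	Injury of unspecified body region	1		false
F01-09	Mental disorders due to known physiological conditions	1		false
R40-46	Symptoms and signs involving cognition, perception, emotional state and behaviour	1		false
G30-32	Other degenerative diseases of the nervous system	1		false
Q90-99	Chromosomal abnormalities, not elsewhere classified	1		false
F50-59	Behavioural syndromes associated with physiological disturbances and physical factors	1		false
G10-14	Systemic atrophies primarily affecting the central nervous system	1		false
G00-99	Diseases of the nervous system	1		false
X-SUBSTANCE-ABUSE	Substance abuse (unspecified)	1		true
X-TBI	Traumatic brain injury	1		true
X-DRUG-INDUCED	Unspecified drug-induced disorders	1		true
X-DRUG-RX-ABUSE	Drug prescription abuse	1		true
MED-ANTIDEPRESSANT	Medication - antidepressants	1		true
MED-ANTIPSYCHOTIC	Medication - antipsychotics	1		true
MED-ANTIANXIETY	Medication - antianxiety	1		true
MED-NEUROLEPTIC	Medication - neuroleptics	1		true
F32	Major depressive disorder, single episode	2	F30-39	false
F31	Bipolar disorder	2	F30-39	false
F34	Persistent mood disorder	2	F30-39	false
F10	Alcohol abuse	2	F10-19	false
F12	Cannabis abuse	2	F10-19	false
F15	Other stimulant related disorders	2	F10-19	false
F19	Other psychoactive substance-related disorders	2	F10-19	false
F20	Schizophrenia	2	F20-29	false
F25	Schizoaffective disorders	2	F20-29	false
F29	Unspecified psychosis not due to a substance or known physiological condition	2	F20-29	false
F41	Other anxiety disorders	2	F40-49	false
F42	Obsessive-compulsive disorder	2	F40-49	false
F43	Reaction to severe stress, and adjustment disorders	2	F40-49	false
F44	Dissociative and conversion disorders	2	F40-49	false
F90	Attention deficit hyperactivity disorder	2	F90-99	false
F91	Conduct disorders	2	F90-99	false
F98	Other behavioural and emotional disorders with onset usually occurring in childhood and adolescence	2	F90-99	false
F84	Pervasive developmental disorder	2	F80-89	false
F60	Specific personality disorders	2	F60-69	false
F63	Habit and impulse disorders	2	F60-69	false
F70	Intellectual disability, mild	2	F70-79	false
F79	Intellectual disability, unspecified	2	F70-79	false
F03	Dementia, unspecified	2	F01-09	false
F50	Eating disorders	2	F50-59	false
G30	Alzheimer disease	2	G30-32	false
T14	Injury of unspecified body region	2	T08-T14	false
R45	Symptoms and signs involving emotional state	2	R40-46	false
Q90	Down syndrome	2	Q90-99	false
F31.9	Bipolar disorder, unspecified	3	F31	false
F32.9	Postpartum depression	3	F32	false
F34.0	Cyclothymic disorder	3	F34	false
F20.9	Schizophrenia, unspecified	3	F20	false
F20.0	Paranoid schizophrenia	3	F20	false
F41.9	Anxiety disorder, unspecified	3	F41	false
F41.0	Panic disorder	3	F41	false
F42.9	Obsessive compulsive disorder, unspecified	3	F42	false
F43.0	Acute stress reaction	3	F43	false
F43.1	Post-traumatic stress disorder	3	F43	false
F44.81	Dissociative identity disorder	3	F44	false
F84.0	Autism	3	F84	false
F84.5	Asperger syndrome	3	F84	false
F91.3	Oppositional defiant disorder	3	F91	false
F91.9	Conduct disorder, unspecified	3	F91	false
F98.9	Unspecified behavioural and emotional disorders with onset usually occurring in childhood and adolescence	3	F98	false
F60.0	Paranoid personality disorder	3	F60	false
F60.3	Borderline personality disorder	3	F60	false
F60.9	Personality disorder, unspecified	3	F60	false
F63.8	Other impulse disorders	3	F63	false
T14.91	Suicide attempt	3	T14	false
R45.85	Suicidal ideations	3	R45	false
G30.9	Alzheimer disease, unspecified	3	G30	false
Q90.9	Down syndrome, unspecified	3	Q90	false
F63.81	Intermittent explosive disorder	4	F63.8	false
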