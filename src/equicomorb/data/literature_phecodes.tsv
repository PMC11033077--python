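# Transcribed metadata: phecodes of index-disorder comorbidities reported in
# at least two prior publications, as mapped to phecode 1.2 definitions.
# Editable data, not code.
phecode	description	category
296.1	Bipolar	Mental disorders
297	Suicidal ideation or attempt	Mental disorders
296	Mood disorders	Mental disorders
316	Substance addiction and disorders	Mental disorders
295.2	Paranoid disorders	Mental disorders
300.9	Posttraumatic stress disorder	Mental disorders
301	Personality disorders	Mental disorders
296.2	Depression	Mental disorders
300	Anxiety disorders	Mental disorders
317	Alcohol-related disorders	Mental disorders
301.2	Antisocial/borderline personality disorder	Mental disorders
318	Tobacco use disorder	Mental disorders
292	Neurological disorders	Mental disorders
291.1	Transient mental disorders due to conditions classified elsewhere	Mental disorders
315.3	Mental retardation	Mental disorders
70	Viral hepatitis	Infectious diseases
345.1	Epilepsy	Neurological
71	HIV disease	Infectious diseases
338.2	Chronic pain	Neurological
250	Diabetes mellitus	Endocrine/metabolic
497	Bronchitis	Respiratory
290.1	Dementias	Mental disorders
495.1	Chronic obstructive asthma	Respiratory
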