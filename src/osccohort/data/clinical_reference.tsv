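patient_id	tnm	history	age	sex	site	stage	profiling
10026E/23	PT2N0	Radio therapy done before surgery	44	male	Right lateral border of tongue	II	normal_only
10175R2/23	PT2N0Mx	Chemo done before surgery	58	female	Tongue left lateral border	II	none
4384A/23	PT2N0	No relevant history	44	male	Right buccal mucosa	II	tumor_only
4741H/23	PT1N0	No relevant history	80	male	Left upper lip	I	tumor_only
4968E/23	PT2N0	Radio therapy done before surgery	49	male	Left lateral border of tongue	II	paired
4975/23	PT2N2b	No relevant history	56	female	Right retromolar trigone	IV	paired
5058F/23	PT4aN1	Hyperthyroidism under medication, surgery post chemo	47	female	Left lower alveolus	IV	tumor_only
5103G/23	PT4aNx	Radio therapy, cancer recurrence, chemo done	53	male	Right upper alveolus	IV	tumor_only
5212E/23	PT2N2b	No relevant history	41	male	Right buccal mucosa	IV	paired
5286G/23	PT4ANb2	Hypertension under medication	46	female	Right buccal mucosa	IV	paired
5288G/23	PT4AN3b	Radio therapy done before surgery	75	male	Left lower alveolus	IV	paired
5521F/23	PT2N2b	Chemo done before surgery	41	male	Right buccal mucosa	IV	paired
6331D/23	PT1N0	Diabetes, hypertension	55	female	Left buccal mucosa	I	paired
6627B/23	PT2N1	Cisplatin poor tolerance	59	female	Right buccal mucosa extending to upper alveolus	III	normal_only
6702E/23	PT2N0	No relevant history	76	female	Right lower alveolus + marginal mandibulectomy	II	tumor_only
6750C/23	PT3N1	Diaphragmatic palsy, adjuvant radio therapy	72	male	Right lateral border of tongue	III	paired
7736J/23	PT4aN2b	No relevant history	80	female	Left buccal mucosa	IV	paired
8412E/23	PT2N0	Diabetic under ayurvedic medication	58	male	Right buccal mucosa	II	paired
9392E/23	PT2N2bMx	Radio therapy done post-surgery	52	male	Lateral border of tongue	IV	none
9465C/23	PT1N1	No relevant history	55	female	Right lower lip	III	paired
9472C/23	PT2N1	No relevant history	69	male	Left buccal mucosa	III	paired
9640E/23	PT2N0	Hypertension under medication	82	male	Lower lip	II	paired
9653E/23	PT3N0	No relevant history	75	male	Left angle of mouth + right buccal mucosa	III	none
9675D/23	PT2N0	No relevant history	50	male	Left lateral border of tongue	II	paired
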