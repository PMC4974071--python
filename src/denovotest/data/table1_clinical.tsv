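feature	1	2	3	4	5	6	7	8	9	10	11
mutation_class	missense	missense	missense	loss of function	loss of function	loss of function	loss of function	loss of function	loss of function	loss of function	loss of function
sex	F	M	F	F	F	F	F	F	M	F	M
microcephaly	-	-	+	+	+	+	+	-	-	NA	NA
intellectual_disability	mild-moderate	moderate-severe	moderate	moderate	moderate	+	moderate	moderate	moderate	severe	NA
sat_independently	7	10	12	NA	11	NA	NA	14	12	NA	NA
walked_independently	20	36	24	22	45	NA	NA	23	36	30	NA
first_words	22	27	36	16	NA	24-30	NA	60	36	NA	NA
downslanting_palpebral_fissures	+	-	-	+	-	NA	+	+	-	NA	NA
epicanthus	-	-	-	-	+	NA	+	-	+	NA	NA
strabismus	+	+	+	+	+	NA	+	+	+	NA	NA
blue_sclera_in_infancy	-	-	-	+	+	+	-	-	-	NA	NA
flat_midface	+	+	+	+	+	NA	-	-	+	NA	NA
thin_upper_lip	+	+	+	+	+	NA	-	+	+	NA	NA
everted_lower_lip	+	+	-	+	-	NA	+	+	+	NA	NA
micro_retrognathia	-	-	-	-	-	retro	-	retro	micro	NA	NA
external_ear_anomalies	-	-	+	+	+	NA	+	-	+	NA	NA
joint_laxity	+	-	+	+	+	NA	+	+	+	NA	NA
short_stature	-	-	-	-	-	+	+	-	-	NA	NA
gait_abnormalities	broad based	broad based, truncal ataxia	-	-	-	NA	-	-	ataxia	NA	NA
asd	-	+	-	-	-	NA	-	-	-	+	+
repetitive_behavior	+	+	+	+	-	NA	-	-	-	-	NA
sleep_disturbance	-	+	+	+	-	NA	-	-	-	+	NA
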