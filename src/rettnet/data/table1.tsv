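patient_id	treatment	age	follow_up	iss_t1	iss_t2	responder
1	Treated	10	14	12	11	Responder
2	Treated	4	13	18	13	Responder
3	Treated	3	11	21	21	Nonresponder
4	Treated	4	7	21	22	Nonresponder
5	Treated	3	12	12	10	Responder
6	Treated	10	7	19	13	Responder
7	Treated	9	15	19	19	Nonresponder
8	Treated	4	13	14	14	Nonresponder
9	Treated	6	14	20	15	Responder
10	Untreated	2	4	12	16	N/A
11	Untreated	2	11	13	18	N/A
12	Untreated	8	13	20	19	N/A
13	Untreated	14	16	14	13	N/A
14	Untreated	6	18	19	19	N/A
15	Untreated	10	12	27	28	N/A
16	Untreated	12	12	20	23	N/A
17	Untreated	12	12	22	22	N/A
18	Untreated	5	12	11	11	N/A
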