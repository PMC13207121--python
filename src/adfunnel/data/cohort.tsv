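participant	sex	age	dance_major	beighton	family_history	complications	ankle_symptom	laxity_events
1	F	20	0	8	1	back pain;wrist pain	lateral ankle laxity	external rotation of shoulder
2	F	23	0	9	1	wrist pain	lateral ankle laxity	full extension of hip
3	F	20	1	9	1	hip pain	lateral ankle laxity	full extension of hip
4	F	23	1	9	1	chronic shoulder dislocations;wrist pain;knee pain	lateral ankle laxity	full extension of hip
5	F	19	1	9	1	back pain;hip pain;knee pain	ankle pain	full extension of hip
6	F	26	1	7	1	knee pain	lateral ankle laxity	full extension of hip
7	F	22	1	9	1	knee pain	lateral ankle laxity	full extension of hip
8	F	22	1	9	1	knee pain	prehallux syndrome
9	F	20	1	9	1	shoulder pain	ankle pain	external rotation of shoulder
10	F	21	1	9	1	back pain;knee pain	lateral ankle laxity	hyperextension of lumbar
11	F	23	1	9	1	back pain;knee pain	ankle pain
12	F	23	1	9	1	chronic shoulder dislocations;knee pain;wrist pain	lateral ankle laxity	hyperextension of lumbar
13	F	20	1	9	1	hip pain;knee pain	ankle pain	full extension of hip
14	F	22	1	9	1	knee pain	lateral ankle laxity
15	M	20	1	9	1	hip pain	lateral ankle laxity	full extension of hip
16	F	25	1	9	1	knee pain	lateral ankle laxity	hyperflexion of wrist
17	F	22	0	7	1	shoulder pain;wrist pain	ankle pain	full extension of hip
18	F	20	0	9	1	wrist pain	lateral ankle laxity	full extension of hip
19	F	22	1	7	1	shoulder pain;knee pain		full extension of hip
20	F	21	1	5	1	wrist pain;hip pain;knee pain	lateral ankle laxity	full extension of hip
21	F	23	0	8	1	hip pain	lateral ankle laxity	full extension of hip
22	M	24	1	9	1	shoulder subluxation	lateral ankle laxity	full extension of hip;hyperextension of lumbar
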