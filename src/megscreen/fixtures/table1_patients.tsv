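patient_id	category
1	24-60 months
2	>60 months
3	>60 months
4	24-60 months
5	>60 months
6	<24 months
7	<24 months
8	24-60 months
9	>60 months
10	24-60 months
11	<24 months
12	<24 months
13	24-60 months
14	>60 months
15	<24 months
16	>60 months
17	<24 months
18	24-60 months
19	>60 months
20	24-60 months
21	<24 months
22	<24 months
23	<24 months
24	>60 months
25	>60 months
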