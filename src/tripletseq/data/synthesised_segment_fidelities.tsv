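regime	position	ref_base	fidelity_pct
defined_triplets	1	A	93.3
defined_triplets	2	A	99.4
defined_triplets	3	A	99.5
defined_triplets	4	G	97.8
defined_triplets	5	C	99.8
defined_triplets	6	U	99.4
defined_triplets	7	U	99.6
defined_triplets	8	G	97.9
defined_triplets	9	A	99.1
defined_triplets	10	G	99.3
defined_triplets	11	A	99.5
defined_triplets	12	G	99.1
defined_triplets	13	C	99.8
defined_triplets	14	A	98.9
defined_triplets	15	U	99.5
defined_triplets	16	C	98.2
defined_triplets	17	U	96.0
defined_triplets	18	U	96.3
random_pool	1	A	92.8
random_pool	2	A	97.0
random_pool	3	A	98.8
random_pool	4	G	99.2
random_pool	5	C	99.5
random_pool	6	U	99.3
random_pool	7	U	99.1
random_pool	8	G	97.8
random_pool	9	A	98.6
random_pool	10	G	99.4
random_pool	11	A	99.1
random_pool	12	G	98.7
random_pool	13	C	94.3
random_pool	14	A	81.4
random_pool	15	U	96.6
random_pool	16	C	97.4
random_pool	17	U	59.8
random_pool	18	U	42.3
low_g_random_pool	1	A	97.3
low_g_random_pool	2	A	98.2
low_g_random_pool	3	A	99.5
low_g_random_pool	4	G	97.3
low_g_random_pool	5	C	99.7
low_g_random_pool	6	U	99.4
low_g_random_pool	7	U	99.6
low_g_random_pool	8	G	97.8
low_g_random_pool	9	A	99.0
low_g_random_pool	10	G	99.3
low_g_random_pool	11	A	98.9
low_g_random_pool	12	G	98.8
low_g_random_pool	13	C	97.6
low_g_random_pool	14	A	97.3
low_g_random_pool	15	U	98.8
low_g_random_pool	16	C	97.4
low_g_random_pool	17	U	73.2
low_g_random_pool	18	U	43.2
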