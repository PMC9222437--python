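snp_id	position	allele1	allele2	codon	aa1	aa2	aliases
rs94930	1	A	G	.	.	.	rs949930
rs713	2	A	C	153	M	L	.
rs731614	3	C	G	.	.	.	.
rs5986963	4	A	G	171	I	V	.
rs5986964	5	T	G	.	.	.	.
rs149897670	6	C	T	174	A	V	.
rs145009674	7	A	G	178	I	V	.
rs155715655	8	G	T	180	A	S	.
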