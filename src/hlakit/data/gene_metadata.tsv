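gene	status	hla_class	map_index	merged_map_group	classical
DPB2	pseudogene	II	1		0
DPA2	pseudogene	II	2		0
DPB1	expressed	II	3		1
DPA1	expressed	II	4		1
DOA	expressed	II	5		0
DMA	expressed	II	6		0
DMB	expressed	II	7		0
TAP2	expressed	other	8		0
TAP1	expressed	other	9		0
DOB	expressed	II	10		0
DQB2	expressed	II	11		0
DQA2	expressed	II	12		0
DQB3	pseudogene	II	13		0
DQB1	expressed	II	14		1
DQA1	expressed	II	15		1
DRB1	expressed	II	16		1
DRB2	pseudogene	II	17		0
DRB3	expressed	II	18	DRB3/4/5	1
DRB4	expressed	II	18	DRB3/4/5	1
DRB5	expressed	II	18	DRB3/4/5	1
DRB6	pseudogene	II	19	DRB6/7	0
DRB7	pseudogene	II	19	DRB6/7	0
DRB8	pseudogene	II	20		0
DRB9	pseudogene	II	21		0
DRA	expressed	II	22		0
MICB	expressed	other	23		0
MICA	expressed	other	24		0
B	expressed	I	25		1
C	expressed	I	26		1
X	pseudogene	I	27		0
E	expressed	I	28		0
T	gene_fragment	I	29		0
W	pseudogene	I	30		0
P	pseudogene	I	31		0
S	gene_fragment	I	32		0
L	pseudogene	I	33		0
N	gene_fragment	I	34		0
J	pseudogene	I	35		0
A	expressed	I	36		1
R	gene_fragment	I	37		0
Y	gene_fragment	I	38		0
V	pseudogene	I	39		0
H	pseudogene	I	40		0
K	pseudogene	I	41		0
U	gene_fragment	I	42		0
G	expressed	I	43		0
F	expressed	I	44		0
HFE	expressed	other	45		0
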