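gene	genome_position	dna	rna	codon_position	confirmed
atpF_ArthCp008	1207	C	T	2	yes
rpoB_ArthCp014	25992	C	T	2	yes
rpoB_ArthCp014	25779	C	T	2	yes
rpoB_ArthCp014	23898	C	T	2	yes
ycf9_ArthCp019	35800	C	T	2	yes
rps14_ArthCp020	37161	C	T	2	yes
rps14_ArthCp020	37092	C	T	2	yes
accD_ArthCp031	57868	C	T	2	yes
psbF_ArthCp038	63985	C	T	2	yes
psbE_ArthCp039	64109	C	T	2	yes
rps18_ArthCp044	67930	A	T	2	new
clpP_ArthCp048	69942	C	T	1	yes
rpoA_ArthCp055	78691	C	T	2	yes
ndhD_ArthCp074	117166	C	T	2	yes
ndhD_ArthCp074	116785	C	T	2	yes
ndhD_ArthCp074	116494	C	T	2	yes
ndhD_ArthCp074	116290	C	T	2	yes
ndhD_ArthCp074	116281	C	T	2	yes
ndhG_ArthCp077	118858	C	T	2	yes
ndhI_ArthCp078	119549	C	T	1	new
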