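# Default codon-anticodon affinity table: Watson-Crick pairs (s=0)
# plus standard third-position wobble pairs at published tAI penalty
# constants (G:U 0.41, I:C 0.28, I:A 0.9999, U:G 0.68), restricted to
# same-family pairs. DNA alphabet, anticodons written 5'->3'.
codon	anticodon	s
AAA	TTT	0.0
AAC	ATT	0.28
AAC	GTT	0.0
AAG	CTT	0.0
AAG	TTT	0.68
AAT	ATT	0.0
AAT	GTT	0.41
ACA	AGT	0.9999
ACA	TGT	0.0
ACC	AGT	0.28
ACC	GGT	0.0
ACG	CGT	0.0
ACG	TGT	0.68
ACT	AGT	0.0
ACT	GGT	0.41
AGA	TCT	0.0
AGC	ACT	0.28
AGC	GCT	0.0
AGG	CCT	0.0
AGG	TCT	0.68
AGT	ACT	0.0
AGT	GCT	0.41
ATA	AAT	0.9999
ATA	TAT	0.0
ATC	AAT	0.28
ATC	GAT	0.0
ATG	CAT	0.0
ATT	AAT	0.0
ATT	GAT	0.41
CAA	TTG	0.0
CAC	ATG	0.28
CAC	GTG	0.0
CAG	CTG	0.0
CAG	TTG	0.68
CAT	ATG	0.0
CAT	GTG	0.41
CCA	AGG	0.9999
CCA	TGG	0.0
CCC	AGG	0.28
CCC	GGG	0.0
CCG	CGG	0.0
CCG	TGG	0.68
CCT	AGG	0.0
CCT	GGG	0.41
CGA	ACG	0.9999
CGA	TCG	0.0
CGC	ACG	0.28
CGC	GCG	0.0
CGG	CCG	0.0
CGG	TCG	0.68
CGT	ACG	0.0
CGT	GCG	0.41
CTA	AAG	0.9999
CTA	TAG	0.0
CTC	AAG	0.28
CTC	GAG	0.0
CTG	CAG	0.0
CTG	TAG	0.68
CTT	AAG	0.0
CTT	GAG	0.41
GAA	TTC	0.0
GAC	ATC	0.28
GAC	GTC	0.0
GAG	CTC	0.0
GAG	TTC	0.68
GAT	ATC	0.0
GAT	GTC	0.41
GCA	AGC	0.9999
GCA	TGC	0.0
GCC	AGC	0.28
GCC	GGC	0.0
GCG	CGC	0.0
GCG	TGC	0.68
GCT	AGC	0.0
GCT	GGC	0.41
GGA	ACC	0.9999
GGA	TCC	0.0
GGC	ACC	0.28
GGC	GCC	0.0
GGG	CCC	0.0
GGG	TCC	0.68
GGT	ACC	0.0
GGT	GCC	0.41
GTA	AAC	0.9999
GTA	TAC	0.0
GTC	AAC	0.28
GTC	GAC	0.0
GTG	CAC	0.0
GTG	TAC	0.68
GTT	AAC	0.0
GTT	GAC	0.41
TAC	ATA	0.28
TAC	GTA	0.0
TAT	ATA	0.0
TAT	GTA	0.41
TCA	AGA	0.9999
TCA	TGA	0.0
TCC	AGA	0.28
TCC	GGA	0.0
TCG	CGA	0.0
TCG	TGA	0.68
TCT	AGA	0.0
TCT	GGA	0.41
TGC	ACA	0.28
TGC	GCA	0.0
TGG	CCA	0.0
TGT	ACA	0.0
TGT	GCA	0.41
TTA	TAA	0.0
TTC	AAA	0.28
TTC	GAA	0.0
TTG	CAA	0.0
TTG	TAA	0.68
TTT	AAA	0.0
TTT	GAA	0.41
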