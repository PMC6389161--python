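# Three-class residue groupings for the seven CTD physicochemical properties.
# Each row partitions the 20 standard amino acids into three disjoint classes.
# Groupings follow the conventional composition/transition/distribution
# encodings used throughout sequence-based protein property prediction.
name	class1	class2	class3
hydrophobicity	RKEDQN	GASTPHY	CLVIMFW
vdW-volume	GASTPDC	NVEQIL	MHKFRYW
polarity	LIFWCMVY	PATGS	HQRKNED
polarizability	GASDT	CPNVEQIL	KMHFRYW
charge	KR	ANCQGHILMFPSTWYV	DE
secondary-structure	EALMQKRH	VIYCWFT	GNPSD
solvent-accessibility	ALFCGIVW	RKQEND	MSPTHY
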