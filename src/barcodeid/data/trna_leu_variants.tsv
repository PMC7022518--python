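# Variable positions of the tRNA-leucine alignment (columns 1502, 1510,
# 1531, 1534). The first row is the reference species with its actual
# bases; '*' marks identity with the reference.
B_nathani	A	T	C	T
F_ostindicae	*	*	T	*
H_kempi	*	*	*	*
L_ruficornis	*	*	*	*
L_pattoni	*	*	*	*
L_saprianovae	*	*	*	*
P_albiceps	*	*	*	*
P_brevicornis	*	*	*	*
P_dux	*	*	*	*
P_misera	*	*	*	*
S_antilope	G	C	*	G
S_inextricata	G	*	*	*
S_seniorwhitei	*	*	*	*
S_princeps	*	*	*	*
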