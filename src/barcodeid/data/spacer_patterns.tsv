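# Aligned intergenic-spacer patterns (alignment columns 1562-1568),
# one row per species; '-' marks an indel.
B_nathani	C-A-CTA
P_albiceps	T-AACTA
P_misera	T-AACTA
P_brevicornis	T-AACTT
P_dux	TTAACTT
H_kempi	TTAATAA
S_princeps	ATAATAA
L_ruficornis	CTCACTA
L_pattoni	--CACTA
L_saprianovae	--CACTA
S_antilope	T-CACTA
S_inextricata	T-TATTA
S_seniorwhitei	T-TATTA
F_ostindicae	ACCACTA
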