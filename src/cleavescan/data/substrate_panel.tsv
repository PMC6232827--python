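name	insert	enzyme	observed_site_kind	inferred
V_center	VLLVSEVL	hNE	insert	no
A_P1_variant	VLLASEVL	hNE	insert_alt_val	no
F_P1_variant	VLLFSEVL	hNE	insert_alt_val	no
I_P1_variant	VLLISEVL	hNE	insert	no
RGG_V	GRGGVGGRG	hNE	insert	no
RGG_A	GRGGAGGRG	hNE	sal_fallback	no
RGG_F	GRGGFGGRG	hNE	sal_fallback	no
RGG_L	GRGGLGGRG	hNE	sal_fallback	no
RGG_VV	GRGGVVGRG	hNE	insert	yes
RGG_VVV	GRGVVVGRG	hNE	insert	yes
RGG_VA	GRGGVAGRG	hNE	insert	yes
RGG_VS	GRGGVSGRG	hNE	insert	yes
RGG_VR	GRGGVRGRG	hNE	insert	yes
RGG_VY	GRGGVYGRG	hNE	insert_weak	yes
RGG_VD	GRGGVDGRG	hNE	insert_weak	yes
RGG_AS	GRGGASGRG	hNE	sal_minor	yes
RGG_FS	GRGGFSGRG	hNE	sal_minor	yes
RGG_IS	GRGGISGRG	hNE	insert	yes
RGG_VSE	GRGGVSEGR	hNE	insert	yes
RGG_VSG	GRGGVSGGR	hNE	insert	yes
RGG_VSR	GRGGVSRGR	hNE	insert	yes
thrombin_site	LTPRGVRL	thrombin	insert	no
hCG_site	VLLFSEVL	hCG	insert	no
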