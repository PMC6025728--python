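gene	P0	P3	P7	P14	P22
Foxp2	no	no	yes	no	yes
Tshz2	no	yes	no	no	yes
Rbfox1	no	no	no	no	no
Eml1	no	no	no	no	no
Hpca	yes	no	no	yes	yes
Plppr3	no	no	no	yes	no
Mapk10	yes	no	yes	yes	yes
Pip5kl1	no	no	no	no	no
Pak6	no	no	no	no	no
Ankrd13b	no	no	no	no	no
Pick1	no	no	no	no	no
Snap91	no	yes	no	no	no
Tusc5	yes	yes	yes	yes	yes
Elfn1	no	no	no	yes	yes
Gabra1	no	no	no	no	yes
Grm4	no	no	no	no	no
Ntrk1	no	no	no	no	no
Pnkd	no	no	no	no	no
Rims1	no	no	no	yes	yes
Fam19a4	no	no	no	no	no
Nptx1	no	no	no	yes	yes
Nptx2	no	no	no	no	no
Sez6l2	yes	no	yes	no	no
Cdh4	yes	yes	no	yes	yes
Pcdh20	no	no	no	yes	no
Rtn4rl2	no	no	yes	no	no
Tmem25	no	no	no	no	no
Tmem91	no	no	yes	yes	no
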