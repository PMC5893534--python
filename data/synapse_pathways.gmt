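ACH	map04725 cholinergic synapse (illustrative rat gene subset)	Chat	Ache	Chrna4	Chrna7	Chrnb2	Chrm1	Chrm2	Slc5a7	Slc18a3	Kcnj3	Gnai1	Adcy1	Prkaca	Camk2a	Pik3ca
GLU	map04724 glutamatergic synapse (illustrative rat gene subset)	Grin1	Grin2a	Grin2b	Gria1	Gria2	Grm1	Grm5	Slc17a7	Slc1a2	Slc1a3	Gls	Shank2	Dlg4	Homer1	Adcy1	Gnai1
GABA	map04727 GABAergic synapse (illustrative rat gene subset)	Gad1	Gad2	Gabra1	Gabra2	Gabrb2	Gabrg2	Gabbr1	Gabbr2	Slc6a1	Slc32a1	Abat	Gphn	Gnai1	Adcy1	Prkcb
DA	map04728 dopaminergic synapse (illustrative rat gene subset)	Th	Ddc	Slc6a3	Slc18a2	Drd1	Drd2	Drd3	Comt	Maoa	Maob	Gnai1	Ppp1r1b	Camk2a	Akt1	Gsk3b
5HT	map04726 serotonergic synapse (illustrative rat gene subset)	Tph2	Ddc	Slc6a4	Slc18a2	Htr1a	Htr1b	Htr2a	Htr2c	Htr3a	Maoa	Comt	Gnai1	Adcy1	Prkca	Cyp2d4
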