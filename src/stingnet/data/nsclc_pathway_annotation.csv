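node,pathway
adp_c,ADP/AMP
adp_ext,ADP/AMP
adpamp,ADP/AMP
aikk,cGAS-STING
akt,EGF/EGFR
ampg,ADP/AMP
ampk,ADP/AMP
atbk,cGAS-STING
atg12,autophagy
atg1210,autophagy
atg125,autophagy
atg12516,autophagy
atg127,autophagy
atg12_gene,autophagy
atg16l,autophagy
atg5,IL-6
atg5,autophagy
atg5_gene,autophagy
atg7,IL-6
atg7,autophagy
atg7_gene,autophagy
atp,cGAS-STING
autoph,autophagy
cgamp_c,cGAS-STING
cgamp_er,cGAS-STING
cgas,cGAS-STING
cgsting_er,cGAS-STING
cgsting_ergic,cGAS-STING
cgsting_gol,cGAS-STING
dnacgas,cGAS-STING
dsdna_c,cGAS-STING
dsdna_pm,cGAS-STING
egf,EGF/EGFR
egfegfr,EGF/EGFR
ergic_c,autophagy
ergic_c,cGAS-STING
ergic_iso,autophagy
ergic_iso,cGAS-STING
ergic_m,autophagy
ergic_m,cGAS-STING
ewc,autophagy
ewc,cGAS-STING
foxo1_c,IL-6
foxo1_c,autophagy
foxo1_n,IL-6
foxo3_c,IL-6
foxo3_c,autophagy
foxo3_n,autophagy
gtp,cGAS-STING
hif1a,EGF/EGFR
hif1a,cGAS-STING
hif1a_i,EGF/EGFR
ifn1_c,IFN1
ifn1_c,cGAS-STING
ifn1_gene,IFN1
ifn1_n,IFN1
ifn1_n,cGAS-STING
ifn1_pm,IFN1
ifnact,IFN1
ifnar,IFN1
ikk_g,LPS/TLR4
ikk_g,cGAS-STING
ikknfkb,cGAS-STING
il10,IL-10
il10b,IL-10
il10r,IL-10
il10rc,IL-10
il6_c,IL-6
il6_c,cGAS-STING
il6_gene,IL-6
il6_n,IL-6
il6_n,cGAS-STING
il6_pm,IL-6
il6r,IL-6
il6rc,IL-6
irak4,LPS/TLR4
irf3,cGAS-STING
jak1tyk2,IFN1
jak1tyk2,IL-10
jak1tyk2,JAK/STAT
lc32,IL-6
lc32,autophagy
lc32_gene,autophagy
lcatg,autophagy
lps,LPS/TLR4
mtorc1,EGF/EGFR
myd88,LPS/TLR4
nfkb,cGAS-STING
p65p50,cGAS-STING
phag,autophagy
phag,cGAS-STING
pi3k,ADP/AMP
pi3k,EGF/EGFR
pirf3_c,cGAS-STING
pirf3_n,cGAS-STING
rec_cgas,cGAS-STING
s12irf9_c,JAK/STAT
s12irf9_n,JAK/STAT
s12irf9_n,cGAS-STING
sec12tmed9,autophagy
sec12tmed9,cGAS-STING
stat12,JAK/STAT
stat3d,IL-6
sting_er,cGAS-STING
sting_gene,cGAS-STING
sting_n,cGAS-STING
tbk_g,LPS/TLR4
tbk_g,cGAS-STING
traf3,LPS/TLR4
ulk1,ADP/AMP
ulk1c,ADP/AMP
ulk1c,autophagy
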