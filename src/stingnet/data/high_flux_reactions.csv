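reaction,flux_mol_per_s
LC3/ATG12/5/16L -> Autophagosome,215000
"STING{""ER membrane""} -> ""cGAMP STING""{""ER membrane""}",119785.7388
FoxO1{Cytoplasm} -> FoxO1{Nucleus},15962.46
ATG12/10 -> ATG12/5,8870.4
ATG5 -> ATG12/5,7884.8
Phagophore -> Autophagosome,5050
FoxO3{Cytoplasm} -> FoxO3{Nucleus},4213.739334
STAT1/2/IRF9{Cytoplasm} -> STAT1/2/IRF9{Nucleus},3520.963037
ATG12/7 -> ATG12/10,3195.52
IFN1{Nucleus} -> IFN1{Cytoplasm},2187.30438
IFN activated -> JAK1/TYK2,1986.823901
"IL6{""Plasma membrane""} + IL6R/gp130 -> IL6/IL6R/gp130",1721.04
"STING{Nucleus} -> STING{""ER membrane""}",1393.470384
"cGAMP{Cytoplasm} -> cGAMP{""ER membrane""}",1327.578
"FoxO1{Nucleus} + ""ATG5 gene"" -> ""ATG5 gene"" + ATG5",1114.342414
"FoxO3{Nucleus} + ""LC3–2 gene"" -> LC3-2 + ""LC3–2 gene""",995.7870612
"ATG12 gene + FoxO3{Nucleus} -> ATG12 + ""ATG12 gene""",995.7870612
"HIF1alpha -> ""HIF1 alpha""",948.9610392
"IFN1{Cytoplasm} -> IFN1{""Plasma membrane""}",803.3688
ERGIC/WIPI2/COP2 -> Phagophore,803.0784
"ERGIC{""ERGIC Isolation membrane""} -> ERGIC{Cytoplasm}",759.64849
STAT3 dimer -> FoxO1{Cytoplasm} + FoxO3{Cytoplasm},595.3331605
"STAT1/2/IRF9{Nucleus} + ""Sting gene"" -> STING{Nucleus} + ""Sting gene""",587.1056789
"HIF1 alpha + ""Sting gene"" -> STING{Nucleus} + ""Sting gene""",557.6449384
"IL6{Cytoplasm} -> IL6{""Plasma membrane""}",540.5768064
"Phos IRF3{Cytoplasm} -> ""Phos IRF3""{Nucleus}",501.8405937
recruited cGAS -> dsDNAcGAScomplex,501
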