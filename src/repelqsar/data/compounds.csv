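id,name,smiles,med_obs,med_pred,units,censored,censor_bound,source_table
5a,N-butyl-N-methyl-hexanamide,CCCCCC(=O)N(C)CCCC,0.117,0.147,umol/cm2,false,,table1
5b,N-butyl-N-ethylhexanamide,CCCCCC(=O)N(CC)CCCC,0.156,0.160,umol/cm2,false,,table1
5c,"N,N-diallylhexanamide",CCCCCC(=O)N(CC=C)CC=C,0.195,0.290,umol/cm2,false,,table1
5g,N-butyl-N-ethyl-2-methylpentanamide,CCCC(C)C(=O)N(CC)CCCC,0.104,0.132,umol/cm2,false,,table1
5i,"N-butyl-N,2-diethylbutanamide",CCC(CC)C(=O)N(CC)CCCC,0.125,0.155,umol/cm2,false,,table1
5j,"N,2-diethyl-N-(2-methyl-2-propenyl)butanamide",CCC(CC)C(=O)N(CC)CC(C)=C,0.375,0.306,umol/cm2,false,,table1
5k,N-butyl-N-ethyl-3-methylbutanamide,CC(C)CC(=O)N(CC)CCCC,0.125,0.164,umol/cm2,false,,table1
5l,"N,N-diisobutyl-3-methylbutanamide",CC(C)CC(=O)N(CC(C)C)CC(C)C,0.406,0.305,umol/cm2,false,,table1
5n,"N-butyl-N-ethyl-2,2-dimethylpropanamide",CC(C)(C)C(=O)N(CC)CCCC,0.286,0.260,umol/cm2,false,,table1
5o,"N-ethyl-2,2-dimethyl-N-(2-methyl-2-propenyl)propanamide",CC(C)(C)C(=O)N(CC)CC(C)=C,0.469,0.512,umol/cm2,false,,table1
5p,"1-(1-azepanyl)-2,2-dimethyl-1-propanone",CC(C)(C)C(=O)N1CCCCCC1,0.313,0.284,umol/cm2,false,,table1
5r,(E)-N-butyl-N-ethyl-2-methyl-2-pentenamide,CC/C=C(\C)C(=O)N(CC)CCCC,0.117,0.119,umol/cm2,false,,table1
5s,(E)-N-ethyl-2-methyl-N-(2-methyl-2-propenyl)-2-pentenamide,CC/C=C(\C)C(=O)N(CC)CC(C)=C,0.182,0.234,umol/cm2,false,,table1
5u,"(E)-2-methyl-N,N-di-2-propenyl-2-pentenamide",CC/C=C(\C)C(=O)N(CC=C)CC=C,0.417,0.216,umol/cm2,false,,table1
5x,N-butyl-N-ethyl-3-methyl-2-butenamide,CC(C)=CC(=O)N(CC)CCCC,0.192,0.145,umol/cm2,false,,table1
5y,N-ethyl-3-methyl-N-(2-methyl-2-propenyl)-2-butenamide,CC(C)=CC(=O)N(CC)CC(C)=C,0.313,0.285,umol/cm2,false,,table1
5z,"N,N-diisobutyl-3-methylcrotonamide",CC(C)=CC(=O)N(CC(C)C)CC(C)C,0.219,0.269,umol/cm2,false,,table1
5e',(E)-N-n-butyl-N-ethyl-2-hexenamide,CCC/C=C/C(=O)N(CC)CCCC,0.274,0.322,umol/cm2,false,,table1
5g',(E)-N-cyclohexyl-N-ethyl-2-hexenamide,CCC/C=C/C(=O)N(CC)C1CCCCC1,0.651,0.414,umol/cm2,false,,table1
5h',N-butyl-N-methyl-5-hexynamide,C#CCCCC(=O)N(C)CCCC,0.182,0.203,umol/cm2,false,,table1
5j',"(E)-N,2-dimethyl-N-octylpent-2-enamide",CC/C=C(\C)C(=O)N(C)CCCCCCCC,0.125,0.195,umol/cm2,false,,table1
5e,N-cyclohexyl-N-ethylhexanamide,CCCCCC(=O)N(CC)C1CCCCC1,0.266,0.205,umol/cm2,false,,table1
5f',"(E)-N,N-di-(2-methylpropyl)-2-hexenamide",CCC/C=C/C(=O)N(CC(C)C)CC(C)C,0.625,0.600,umol/cm2,false,,table1
5f,N-ethyl-N-phenylhexanamide,CCCCCC(=O)N(CC)c1ccccc1,0.625,0.257,umol/cm2,false,,table1
5m,N-cyclohexyl-N-ethyl-3-methylbutanamide,CC(C)CC(=O)N(CC)C1CCCCC1,0.172,0.211,umol/cm2,false,,table1
5q,N-butyl-N-ethyl-2-methylbenzamide,CCCCN(CC)C(=O)c1ccccc1C,0.156,0.176,umol/cm2,false,,table1
5v,N-ethyl-2-methyl-N-(2-methyl-2-propenyl)benzamide,C=C(C)CN(CC)C(=O)c1ccccc1C,0.145,0.093,umol/cm2,false,,table1
5w,N-ethyl-2-methyl-N-phenylbenzamide,CCN(c1ccccc1)C(=O)c1ccccc1C,5.160,7.012,umol/cm2,false,,table1
5k',N-cyclohexyl-N-methylheptanamide,CCCCCCC(=O)N(C)C1CCCCC1,0.172,0.127,umol/cm2,false,,table1
5l',(E)-N-cyclohexyl-N-ethyl-2-methylpent-2-enamide,CC/C=C(\C)C(=O)N(CC)C1CCCCC1,0.140,0.153,umol/cm2,false,,table1
5d,hexahydro-1-(1-oxohexyl)-1H-azepine,CCCCCC(=O)N1CCCCCC1,0.033,0.108,umol/cm2,false,,table1
5h,1-(1-azepanyl)-2-methyl-1-pentanone,CCCC(C)C(=O)N1CCCCCC1,0.102,0.089,umol/cm2,false,,table1
5t,(E)-1-(1-azepanyl)-2-methyl-2-penten-1-one,CC/C=C(\C)C(=O)N1CCCCCC1,0.098,0.089,umol/cm2,false,,table1
5a',hexahydro-1-(3-methylcrotonoyl)-1H-azepine,CC(C)=CC(=O)N1CCCCCC1,0.140,0.109,umol/cm2,false,,table1
5b',N-butyl-N-ethyl-cinnamamide,CCCCN(CC)C(=O)/C=C/c1ccccc1,10.750,15.268,umol/cm2,false,,table1
5c',"N,N-bis(2-methylpropyl)-3-phenyl-2-propenamide",CC(C)CN(CC(C)C)C(=O)/C=C/c1ccccc1,20.125,28.443,umol/cm2,false,,table1
5d',"N-ethyl-N,3-diphenyl-2-propenamide",CCN(c1ccccc1)C(=O)/C=C/c1ccccc1,20.250,24.890,umol/cm2,false,,table1
5i',"N,3-dicyclohexyl-N-ethylpropanamide",CCN(C1CCCCC1)C(=O)CCC1CCCCC1,20.500,24.830,umol/cm2,false,,table1
C39,3-cyclohexyl-N-methyl-N-octylpropanamide,CCCCCCCCN(C)C(=O)CCC1CCCCC1,25.000,31.596,umol/cm2,true,25.0,table1
C40,4-methyl-N-phenylbenzamide,Cc1ccc(C(=O)Nc2ccccc2)cc1,25.000,14.768,umol/cm2,true,25.0,table1
C41,2-methyl-N-phenylbenzamide,Cc1ccccc1C(=O)Nc1ccccc1,25.000,17.736,umol/cm2,true,25.0,table1
C42,N-cyclohexyl-N-isopropyl-4-methyloctanamide,CCCCC(C)CCC(=O)N(C(C)C)C1CCCCC1,25.000,28.247,umol/cm2,true,25.0,table1
C43,"N,N-dicyclohexyl-4-methyloctanamide",CCCCC(C)CCC(=O)N(C1CCCCC1)C1CCCCC1,25.000,20.564,umol/cm2,true,25.0,table1
DEET,"N,N-diethyl-3-methylbenzamide",CCN(CC)C(=O)c1cccc(C)c1,0.052,0.053,umol/cm2,false,,table1
YF2,2-methyl-4-nitro-3-nonanol,CCCCCC([N+](=O)[O-])C(O)C(C)C,0.047,0.043,umol/cm2,false,,table2
YF4,dibutyl fumarate,CCCCOC(=O)/C=C/C(=O)OCCCC,0.047,0.036,umol/cm2,false,,table2
YF6,2-hydroxyethyl 2-hydroxybenzoate,OCCOC(=O)c1ccccc1O,2.500,2.716,umol/cm2,false,,table2
YF7,2-chlorophenethyl alcohol,OCCc1ccccc1Cl,0.101,0.078,umol/cm2,false,,table2
YF8,2-bromophenethyl alcohol,OCCc1ccccc1Br,0.049,0.076,umol/cm2,false,,table2
YF12,2-ethyl-1-hexanol,CCCCC(CC)CO,1.875,1.351,umol/cm2,false,,table2
YF15,2-anilinoethanol,OCCNc1ccccc1,1.875,0.679,umol/cm2,false,,table2
YF16,3-phenyl-1-propanol,OCCCc1ccccc1,0.406,0.531,umol/cm2,false,,table2
YF18,"1,2-pentanediol",CCCC(O)CO,2.500,2.458,umol/cm2,false,,table2
YF19,"1,2,3,4-tetrahydro-1-naphthol",OC1CCCc2ccccc21,0.078,0.068,umol/cm2,false,,table2
YF20,2-phenoxyethanol,OCCOc1ccccc1,0.563,0.578,umol/cm2,false,,table2
YF21,2-(N-ethylanilino)-ethanol,CCN(CCO)c1ccccc1,0.156,0.113,umol/cm2,false,,table2
YF22,2-(p-chlorophenoxy)-ethanol,OCCOc1ccc(Cl)cc1,0.219,0.240,umol/cm2,false,,table2
YF23,2-cyclohexyl-cyclohexanol,OC1CCCCC1C1CCCCC1,0.437,0.513,umol/cm2,false,,table2
YF24,2-phenyl-cyclohexanol,OC1CCCCC1c1ccccc1,0.047,0.058,umol/cm2,false,,table2
YF25,"1,2,3,4-tetrahydro-2-naphthol",OC1CCc2ccccc2C1,0.062,0.078,umol/cm2,false,,table2
YF27,"2-(2-bromophenyl)-1,3-dioxolane",Brc1ccccc1C1OCCO1,0.156,0.169,umol/cm2,false,,table2
YF39,(2-iodophenyl)methanol,OCc1ccccc1I,0.070,0.066,umol/cm2,false,,table2
NR1,2-nonanone,CCCCCCCC(C)=O,0.437,0.285,umol/cm2,false,,table2
NR2,2-undecanone,CCCCCCCCCC(C)=O,0.109,0.086,umol/cm2,false,,table2
NR3,valencene,CC1CCC2(C)CCC(CC2=C1)C(C)=C,0.138,0.157,umol/cm2,false,,table2
NR4,methyl salicylate,COC(=O)c1ccccc1O,0.312,0.278,umol/cm2,false,,table2
NR5,carvacrol,Cc1ccc(C(C)C)cc1O,0.013,0.013,umol/cm2,false,,table2
NR6,benzyl benzoate,O=C(OCc1ccccc1)c1ccccc1,0.023,0.071,umol/cm2,false,,table2
NR7,thymol,Cc1ccc(C(C)C)c(O)c1,0.031,0.050,umol/cm2,false,,table2
NR8,carvacrol methyl ether,COc1cc(C)ccc1C(C)C,0.063,0.050,umol/cm2,false,,table2
NR9,2-nonanol,CCCCCCCC(C)O,0.066,0.084,umol/cm2,false,,table2
X1,,,,0.307,ug/cm2,true,2.5,table5
X2,,,,,ug/cm2,true,2.5,table5
X4,,,0.078,0.03,ug/cm2,false,,table5
X5,,,0.156,0.067,ug/cm2,false,,table5
X7,,,0.417,0.112,ug/cm2,false,,table5
X8,,,,,ug/cm2,true,2.5,table5
X9,,,,0.182,ug/cm2,true,2.5,table5
X10,,,1.25,0.33,ug/cm2,false,,table5
X11,,,,,ug/cm2,true,2.5,table5
X12,,,,0.096,ug/cm2,true,2.5,table5
X14,,,,,ug/cm2,true,2.5,table5
X15,,,,,ug/cm2,true,2.5,table5
X16,,,0.261,0.303,ug/cm2,false,,table5
X17,,,1.667,0.082,ug/cm2,false,,table5
X18,,,,0.219,ug/cm2,true,2.5,table5
X19,,,,,ug/cm2,true,2.5,table5
X20,,,,,ug/cm2,true,2.5,table5
X21,,,,2.786,ug/cm2,true,2.5,table5
X23,,,0.039,0.061,ug/cm2,false,,table5
X24,,,,0.036,ug/cm2,true,2.5,table5
X25,,,1.87,0.198,ug/cm2,false,,table5
X26,,,,0.01,ug/cm2,true,2.5,table5
X27,,,,,ug/cm2,true,2.5,table5
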