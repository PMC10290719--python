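# Synthetic drug-like compound library (scaffold x substituent enumeration);
# canonical isomeric SMILES, one per line. Generated fixture, not real ligands.
CN(C)c1ccccc1
O=C(O)c1ccccc1
NC(=O)c1ccccc1
c1ccc(-c2ccccc2)cc1
Brc1ccccc1
CN(C)CCc1ccccc1
CCOc1ccccc1
c1ccc(-c2ccncc2)cc1
CC(C)c1ccccc1
NC(=O)Cc1ccccc1
COC(=O)c1ccccc1
FC(F)(F)c1ccccc1
CCCc1ccccc1
c1ccc(-c2cccnc2)cc1
c1cncc(-c2ccncc2)c1
COC(=O)c1cccnc1
CN(C)CCc1cccnc1
CC(C)c1cccnc1
CS(=O)(=O)c1cccnc1
FC(F)(F)c1cccnc1
O=C(O)c1cccnc1
Brc1cccnc1
NC(=O)Cc1cccnc1
CN(C)c1cccnc1
CCCc1cccnc1
c1cncc(CCN2CCOCC2)c1
CNc1nccc(OC)n1
CN(C)CCc1nccc(C(=O)O)n1
CN(C)c1ccnc(C(F)(F)F)n1
OCc1nccc(C(F)(F)F)n1
CCCc1nccc(C#N)n1
COc1ccnc(C(N)=O)n1
COC(=O)c1nccc(Br)n1
N#Cc1ccnc(C(N)=O)n1
CS(=O)(=O)c1nccc(CO)n1
CCc1nccc(CC(N)=O)n1
NC(=O)c1ccnc(N)n1
Fc1ccnc(-c2ccncc2)n1
CCOc1ccnc(C)n1
CNc1cccc2[nH]ccc12
CCc1cccc2[nH]ccc12
N#Cc1cccc2[nH]ccc12
CC(C)c1cccc2[nH]ccc12
Cc1cccc2[nH]ccc12
COc1cccc2[nH]ccc12
Clc1cccc2[nH]ccc12
Fc1cccc2[nH]ccc12
O=C(O)c1cccc2[nH]ccc12
CN(C)CCc1cccc2[nH]ccc12
c1ccc(-c2cccc3[nH]ccc23)cc1
Nc1cccc2[nH]ccc12
NC(=O)Cc1cccc2[nH]ccc12
Cc1cccc2ncccc12
CN(C)c1cccc2ncccc12
FC(F)(F)c1cccc2ncccc12
O=C(O)c1cccc2ncccc12
CNc1cccc2ncccc12
CS(=O)(=O)c1cccc2ncccc12
CCCc1cccc2ncccc12
Clc1cccc2ncccc12
c1ccc(-c2cccc3ncccc23)cc1
NC(=O)c1cccc2ncccc12
CCOc1cccc2ncccc12
CC(C)c1cccc2ncccc12
N#Cc1cccc2ncccc12
O=C(CO)c1ccccc1-c1ccncc1
CNC(=O)c1ccccc1CO
COc1ccccc1C(=O)F
N#Cc1ccccc1C(=O)CC(N)=O
CCCc1ccccc1C(=O)C(C)C
N#Cc1ccccc1C(=O)F
CS(=O)(=O)C(=O)c1ccccc1-c1ccccc1
CNc1ccccc1C(=O)C(=O)O
CCCc1ccccc1C(=O)c1ccncc1
CNC(=O)c1ccccc1C(N)=O
NC(=O)C(=O)c1ccccc1CCN1CCOCC1
CCC(=O)c1ccccc1N
CNC(=O)c1ccccc1C#N
Brc1cccs1
C1=CC=Cc2sccc2C=C1
CCOc1cccs1
NC(=O)c1cccs1
CC(C)c1cccs1
C1=Cc2sccc2C=CN=C1
COC(=O)c1cccs1
CN(C)c1cccs1
NC(=O)Cc1cccs1
CN(C)CCc1cccs1
FC(F)(F)c1cccs1
O=C(O)c1cccs1
CS(=O)(=O)c1cccs1
CCCn1nccc1C(N)=O
CCCC1=CC=NC=Cc2ccnn21
CC(C)n1nccc1Br
COC(=O)c1ccnn1CCN(C)C
Cn1nccc1-c1ccncc1
CCOc1ccnn1CC(N)=O
NC(=O)c1ccnn1C(N)=O
NC(=O)Cn1nccc1-c1ccncc1
CCc1ccnn1N(C)C
CCn1nccc1-c1ccncc1
O=C(O)c1ccnn1C(F)(F)F
Brn1nccc1-c1ccccc1
CCOc1ccnn1C#N
O=C1NC(=O)c2ccccc21
CN(C)CCNC(=O)c1ccccc1
O=C(NBr)c1ccccc1
O=C(NCl)c1ccccc1
O=C(NCCN1CCOCC1)c1ccccc1
O=C(NC(F)(F)F)c1ccccc1
O=C(NCO)c1ccccc1
CCONC(=O)c1ccccc1
CCCNC(=O)c1ccccc1
O=C(Nc1ccncc1)c1ccccc1
COC(=O)NC(=O)c1ccccc1
N#CNC(=O)c1ccccc1
CNC(=O)c1ccccc1
NC(=O)NC(=O)c1ccccc1
CCONS(=O)(=O)c1ccccc1
CC(C)NS(=O)(=O)c1ccccc1
CNNS(=O)(=O)c1ccccc1
NC(=O)CNS(=O)(=O)c1ccccc1
O=S(=O)(NCO)c1ccccc1
N#CNS(=O)(=O)c1ccccc1
COC(=O)NS(=O)(=O)c1ccccc1
O=S(=O)(NF)c1ccccc1
O=C(O)NS(=O)(=O)c1ccccc1
O=S(=O)(NBr)c1ccccc1
O=S(=O)(NCCN1CCOCC1)c1ccccc1
CONS(=O)(=O)c1ccccc1
CCNS(=O)(=O)c1ccccc1
c1ccc(Nc2ncccn2)cc1
CN(C)CCc1cccc(Oc2ccccc2)c1
CCCc1cccc(Oc2ccccc2)c1
NC(=O)Cc1cccc(Oc2ccccc2)c1
O=C(O)c1cccc(Oc2ccccc2)c1
Cc1cccc(Oc2ccccc2)c1
N#Cc1cccc(Oc2ccccc2)c1
NC(=O)c1cccc(Oc2ccccc2)c1
Clc1cccc(Oc2ccccc2)c1
c1ccc(Oc2cccc(-c3ccncc3)c2)cc1
COc1cccc(Oc2ccccc2)c1
COC(=O)c1cccc(Oc2ccccc2)c1
CCc1cccc(Oc2ccccc2)c1
FC(F)(F)c1cccc(Oc2ccccc2)c1
CCON1CCCCC1
C1CCN(CCN2CCOCC2)CC1
COC(=O)N1CCCCC1
c1ccc(N2CCCCC2)cc1
c1cc(N2CCCCC2)ccn1
NC(=O)N1CCCCC1
CS(=O)(=O)N1CCCCC1
CN(C)N1CCCCC1
NC(=O)CN1CCCCC1
BrN1CCCCC1
CC(C)N1CCCCC1
CCCN1CCCCC1
O=C(O)N1CCCCC1
COC(=O)c1nc2ccccc2o1
c1ccc2oc(CCN3CCOCC3)nc2c1
FC(F)(F)c1nc2ccccc2o1
CCOc1nc2ccccc2o1
Cc1nc2ccccc2o1
CNc1nc2ccccc2o1
Clc1nc2ccccc2o1
O=C(O)c1nc2ccccc2o1
CC(C)c1nc2ccccc2o1
CCCc1nc2ccccc2o1
NC(=O)c1nc2ccccc2o1
N#Cc1nc2ccccc2o1
c1ccc(-c2nc3ccccc3o2)cc1
COc1nc2ccccc2s1
O=C(O)c1nc2ccccc2s1
NC(=O)Cc1nc2ccccc2s1
Brc1nc2ccccc2s1
CC(C)c1nc2ccccc2s1
Cc1nc2ccccc2s1
Nc1nc2ccccc2s1
CCOc1nc2ccccc2s1
CNc1nc2ccccc2s1
CN(C)c1nc2ccccc2s1
NC(=O)c1nc2ccccc2s1
Clc1nc2ccccc2s1
CCCc1nc2ccccc2s1
CONC(=O)/C=C/c1ccccc1
CS(=O)(=O)NC(=O)/C=C/c1ccccc1
O=C(/C=C/c1ccccc1)NBr
CCNC(=O)/C=C/c1ccccc1
O=C(/C=C/c1ccccc1)NCCN1CCOCC1
CNNC(=O)/C=C/c1ccccc1
O=C(/C=C/c1ccccc1)NF
CCONC(=O)/C=C/c1ccccc1
O=C(/C=C/c1ccccc1)NCl
COC(=O)NC(=O)/C=C/c1ccccc1
CNC(=O)/C=C/c1ccccc1
CN(C)NC(=O)/C=C/c1ccccc1
CC(C)NC(=O)/C=C/c1ccccc1
Fc1ccc(Nc2ncnc3[nH]ccc23)cc1
c1ccc(-n2cnc3ccccc32)cc1
COC(=O)c1cc(=O)c2ccccc2o1
O=c1cc(CO)oc2ccccc12
O=c1cc(Cl)oc2ccccc12
CC(C)c1cc(=O)c2ccccc2o1
NC(=O)c1cc(=O)c2ccccc2o1
CCOc1cc(=O)c2ccccc2o1
O=c1cc(-c2ccccc2)oc2ccccc12
CNc1cc(=O)c2ccccc2o1
CCc1cc(=O)c2ccccc2o1
O=c1cc(C(F)(F)F)oc2ccccc12
O=c1cc(Br)oc2ccccc12
Nc1cc(=O)c2ccccc2o1
O=C(O)c1cc(=O)c2ccccc2o1
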