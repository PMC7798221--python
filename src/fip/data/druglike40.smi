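CC(=O)Oc1ccccc1C(=O)O aspirin
CC(=O)Nc1ccc(O)cc1 paracetamol
Cn1cnc2c1c(=O)n(C)c(=O)n2C caffeine
CC(C)Cc1ccc(cc1)C(C)C(=O)O ibuprofen
COc1ccc2cc(ccc2c1)C(C)C(=O)O naproxen
O=C(O)c1ccccc1O salicylic_acid
CCOC(=O)c1ccc(N)cc1 benzocaine
CCN(CC)CCOC(=O)c1ccc(N)cc1 procaine
CCN(CC)CC(=O)Nc1c(C)cccc1C lidocaine
CN1CCCC1c1cccnc1 nicotine
CN1c2ccc(Cl)cc2C(=NCC1=O)c1ccccc1 diazepam
CN(C)CCOC(c1ccccc1)c1ccccc1 diphenhydramine
CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O warfarin
O=c1ccc2ccccc2o1 coumarin
CCC1(c2ccccc2)C(=O)NC(=O)NC1=O phenobarbital
CCC1(CC)C(=O)NC(=O)NC1=O barbital
CN(C)C(=N)NC(=N)N metformin
CC(C)NCC(O)COc1ccc(CC(N)=O)cc1 atenolol
CC(C)NCC(O)COc1cccc2ccccc12 propranolol
COCCc1ccc(OCC(O)CNC(C)C)cc1 metoprolol
Cc1cc(no1)NS(=O)(=O)c1ccc(N)cc1 sulfamethoxazole
COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OC trimethoprim
CNCCC(Oc1ccc(cc1)C(F)(F)F)c1ccccc1 fluoxetine
OC(Cn1cncn1)(Cn1cncn1)c1ccc(F)cc1F fluconazole
OC(=O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O ciprofloxacin
CC(C(=O)O)c1cccc(C(=O)c2ccccc2)c1 ketoprofen
Cc1ccc(C)c(OCCCC(C)(C)C(=O)O)c1 gemfibrozil
CCOC(=O)C(C)(C)Oc1ccc(Cl)cc1 clofibrate
CCCCNC(=O)NS(=O)(=O)c1ccc(C)cc1 tolbutamide
O=C1NC(=O)C(c2ccccc2)(c2ccccc2)N1 phenytoin
NC(=O)N1c2ccccc2C=Cc2ccccc21 carbamazepine
Cn1c(=O)c2[nH]cnc2n(C)c1=O theophylline
O=c1cc[nH]c(=O)[nH]1 uracil
Nc1ncnc2[nH]cnc12 adenine
COc1ccc2c(c1)c(CC(=O)O)c(C)n2C(=O)c1ccc(Cl)cc1 indomethacin
Cc1cccc(Nc2ccccc2C(=O)O)c1C mefenamic_acid
CC1=CC(=O)N(c2ccccc2)N1C antipyrine
NNC(=O)c1ccncc1 isoniazid
NC(=O)c1cnccn1 pyrazinamide
CCn1cc(C(=O)O)c(=O)c2ccc(C)nc21 nalidixic_acid
OCC(NC(=O)C(Cl)Cl)C(O)c1ccc(cc1)[N+](=O)[O-] chloramphenicol_core
Nc1ccc(cc1)S(=O)(=O)c1ccc(N)cc1 dapsone
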