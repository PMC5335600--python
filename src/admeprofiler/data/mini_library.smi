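# Mini-library of common, readily obtainable drug and drug-like molecules.
# Used to build the default fragment-frequency table for the SA score and as
# a general-purpose fixture set. One SMILES + name per line.
CC(=O)Oc1ccccc1C(=O)O aspirin
CC(=O)Nc1ccc(O)cc1 paracetamol
CC(C)Cc1ccc(cc1)C(C)C(=O)O ibuprofen
Cn1cnc2c1c(=O)n(C)c(=O)n2C caffeine
CN1CCC[C@H]1c1cccnc1 nicotine
OC(=O)c1ccccc1O salicylic_acid
NC(=O)c1ccccc1 benzamide
c1ccc2c(c1)cccc2O naphthol
CCN(CC)CCNC(=O)c1ccc(N)cc1 procainamide
CC(N)Cc1ccccc1 amphetamine
CNC[C@H](O)c1ccc(O)c(O)c1 epinephrine
NCCc1ccc(O)c(O)c1 dopamine
OCCN1CCN(CCCN2c3ccccc3Sc3ccc(Cl)cc32)CC1 perphenazine_core
Clc1ccccc1-c1nc2ccccc2[nH]1 clemizole_core
CC(C)NCC(O)COc1ccc(CC(N)=O)cc1 atenolol
CC(C)NCC(O)COc1cccc2ccccc12 propranolol
COc1ccc2cc(ccc2c1)C(C)C(=O)O naproxen
OC(=O)Cc1ccccc1Nc1c(Cl)cccc1Cl diclofenac
CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O penicillin_G
CC1(C)SC2C(NC(=O)C(N)c3ccccc3)C(=O)N2C1C(=O)O ampicillin
Cc1ccc(cc1)S(=O)(=O)NC(=O)NCCCC tolbutamide
NS(=O)(=O)c1cc2c(cc1Cl)NCNS2(=O)=O hydrochlorothiazide
CN(C)CCCN1c2ccccc2CCc2ccccc21 imipramine
CN(C)CCC=C1c2ccccc2CCc2ccccc21 amitriptyline
Clc1ccc2c(c1)C(=NCc1ccccc1)c1ccccc1N2 core_benzodiazepine
CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21 diazepam
OC(=O)C1CCCCC1 cyclohexanecarboxylic_acid
Nc1ccc(cc1)S(N)(=O)=O sulfanilamide
COc1cc2c(cc1OC)C(=O)C(CC1CCN(Cc3ccccc3)CC1)C2 donepezil
CCOC(=O)C1=C(C)NC(C)=C(C1c1ccccc1[N+](=O)[O-])C(=O)OC nifedipine_analog
CC(CS)C(=O)N1CCCC1C(=O)O captopril
NC(N)=Nc1nc(CSCCC(N)=N)cs1 core_guanidinothiazole
CC(=O)NCCc1c[nH]c2ccc(OC)cc12 melatonin
NC(Cc1c[nH]c2ccccc12)C(=O)O tryptophan
NC(Cc1ccc(O)cc1)C(=O)O tyrosine
NC(CC(=O)O)C(=O)O aspartic_acid
NC(CCC(=O)O)C(=O)O glutamic_acid
CC(C)CC(N)C(=O)O leucine
NC(C(=O)O)c1ccccc1 phenylglycine
OCC1OC(O)C(O)C(O)C1O glucose
OCC1OC(OC2C(O)C(O)C(O)OC2CO)C(O)C(O)C1O disaccharide
CN1CCCC1=O n_methylpyrrolidone
O=C1CCCCC1 cyclohexanone
c1ccc(cc1)-c1ccccc1 biphenyl
c1ccc2ccccc2c1 naphthalene
Oc1ccccc1 phenol
Nc1ccccc1 aniline
Clc1ccccc1 chlorobenzene
CCOCC diethyl_ether
CCO ethanol
CC(C)O isopropanol
CC(=O)C acetone
CC(=O)OCC ethyl_acetate
CCCCCC hexane
C1CCCCC1 cyclohexane
c1ccncc1 pyridine
c1ccc2[nH]ccc2c1 indole
c1ccc2nc(N)ccc2c1 aminoquinoline
c1cnc2[nH]cnc2c1 core_purine
Cn1ccnc1 n_methylimidazole
O=c1cc[nH]c(=O)[nH]1 uracil
Cc1c[nH]c(=O)[nH]c1=O thymine
Nc1nc2[nH]cnc2c(=O)[nH]1 guanine
Nc1ccn(c(=O)n1)C cytosine_methyl
OCC(O)CO glycerol
OCCO ethylene_glycol
C(C(=O)O)C(=O)O malonic_acid
OC(=O)CCC(=O)O succinic_acid
OC(C(=O)O)C(O)C(=O)O tartaric_acid
CC(O)C(=O)O lactic_acid
OC(=O)C=Cc1ccccc1 cinnamic_acid
COc1ccc(C=CC(=O)O)cc1 methoxycinnamic_acid
COc1cc(C=O)ccc1O vanillin
Oc1ccc(C=O)cc1 hydroxybenzaldehyde
CC(=O)c1ccccc1 acetophenone
OCc1ccccc1 benzyl_alcohol
O=Cc1ccccc1 benzaldehyde
OC(=O)c1ccccc1 benzoic_acid
COC(=O)c1ccccc1 methyl_benzoate
CC(C)(C)NCC(O)c1ccc(O)c(CO)c1 salbutamol
CNCC(O)c1ccc(O)c(O)c1 core_catecholamine
CN1CCC23c4c5ccc(O)c4OC2C(O)C=CC3C1C5 morphine
COc1ccc2CC3N(C)CCC45C3Cc3ccc(OC)c(c34)Oc1c25 core_opioid
CCC(=O)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1 fentanyl
CN(C)C(=O)Cc1ccccc1 phenylacetamide
CC(C)(C)c1ccc(O)cc1 tert_butylphenol
CC(C)Cc1ccccc1 isobutylbenzene
FC(F)(F)c1ccccc1 trifluorotoluene
Fc1ccc(cc1)C(=O)c1ccc(F)cc1 difluorobenzophenone
O=C(c1ccccc1)c1ccccc1 benzophenone
N#Cc1ccccc1 benzonitrile
[O-][N+](=O)c1ccccc1 nitrobenzene
CS(=O)(=O)c1ccccc1 methylsulfonylbenzene
NS(=O)(=O)c1ccccc1 benzenesulfonamide
CSc1ccccc1 thioanisole
c1ccsc1 thiophene
c1ccoc1 furan
c1cc[nH]c1 pyrrole
c1cscn1 thiazole
c1cnc[nH]1 imidazole
c1ccc(cc1)n1cccc1 phenylpyrrole
OC1CCCCC1 cyclohexanol
NC1CCCCC1 cyclohexylamine
C1CCNCC1 piperidine
C1CCOCC1 tetrahydropyran
C1CNCCN1 piperazine
C1COCCN1 morpholine
O=C1CCCN1 pyrrolidinone
O=C1NC(=O)NC(=O)C1(CC)c1ccccc1 phenobarbital
CCC1(CC)C(=O)NC(=O)NC1=O barbital
CC12CCC3c4ccc(O)cc4CCC3C1CCC2O estradiol
CC12CCC(=O)C=C1CCC1C2CCC2(C)C1CCC2(O)C#C core_norethindrone
CC(C)C1CCC(C)CC1O menthol
CC1=CCC(CC1)C(C)(C)O terpineol
CC(C)=CCCC(C)=CCO geraniol
C1CC2CCC1C2 norbornane_bridged
C1CC2(CC1)CCCC2 spiro_decane
C1CCCCCCCCC1 cyclodecane_macro_precursor
O=C1CCCCCCCCCCC1 cyclododecanone_macro
CC(C)(C)OC(=O)NC(Cc1ccccc1)C(=O)O boc_phenylalanine
CC(C)(C)OC(=O)N1CCCC1C(=O)O boc_proline
CN1CCN(CC1)c1ccc(cc1)C(=O)N piperazinylbenzamide
Clc1cccc(Cl)c1-n1ccnc1 dichlorophenylimidazole
COc1ccccc1OCCNCC(O)COc1cccc2[nH]ccc12 core_carvedilol
CC(=O)SC1CC2=CC(=O)CCC2(C)C2CCC3(C)C(CCC3(C)O)C12 core_spironolactone
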