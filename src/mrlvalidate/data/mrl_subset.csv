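analyte,species,matrix,mrl_ug_kg
sulfamethazine,bovine,muscle,100
sulfamethazine,bovine,milk,100
sulfadimethoxine,bovine,muscle,100
sulfadimethoxine,bovine,milk,100
sulfadiazine,bovine,muscle,100
sulfadiazine,bovine,milk,100
penicillin G,bovine,muscle,50
penicillin G,bovine,milk,4
amoxicillin,bovine,muscle,50
amoxicillin,bovine,milk,4
ampicillin,bovine,muscle,50
ampicillin,bovine,milk,4
cloxacillin,bovine,muscle,300
cloxacillin,bovine,milk,30
oxacillin,bovine,muscle,300
oxacillin,bovine,milk,30
dicloxacillin,bovine,muscle,300
dicloxacillin,bovine,milk,30
nafcillin,bovine,muscle,300
nafcillin,bovine,milk,30
oxytetracycline,bovine,muscle,100
oxytetracycline,bovine,milk,100
tetracycline,bovine,muscle,100
tetracycline,bovine,milk,100
chlortetracycline,bovine,muscle,100
chlortetracycline,bovine,milk,100
doxycycline,bovine,muscle,100
enrofloxacin,bovine,muscle,100
enrofloxacin,bovine,milk,100
ciprofloxacin,bovine,muscle,100
ciprofloxacin,bovine,milk,100
danofloxacin,bovine,muscle,200
danofloxacin,bovine,milk,30
marbofloxacin,bovine,muscle,150
marbofloxacin,bovine,milk,75
flumequine,bovine,muscle,200
flumequine,bovine,milk,50
oxolinic acid,bovine,muscle,100
tylosin A,bovine,muscle,100
tylosin A,bovine,milk,50
spiramycin,bovine,muscle,200
spiramycin,bovine,milk,200
tilmicosin,bovine,muscle,50
tilmicosin,bovine,milk,50
lincomycin,bovine,muscle,100
lincomycin,bovine,milk,150
trimethoprim,bovine,muscle,50
trimethoprim,bovine,milk,50
florfenicol,bovine,muscle,200
cefquinome,bovine,muscle,50
cefquinome,bovine,milk,20
ceftiofur,bovine,muscle,1000
ceftiofur,bovine,milk,100
cefalonium,bovine,milk,20
cefacetrile,bovine,milk,125
cefazolin,bovine,milk,50
cefoperazone,bovine,milk,50
cephapirin,bovine,milk,60
cefalexin,bovine,muscle,200
cefalexin,bovine,milk,100
tiamulin,porcine,muscle,100
valnemulin,porcine,muscle,50
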