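analyte,matrix,cv_r_pooled,cv_wr_pooled,recovery,me_percent,fitness
sulfaguanidine,muscle,5.8,10,83,-14,confirmation
sulfaguanidine,milk,5.0,14,61,253,confirmation
florfenicol amine,muscle,3.2,6.1,85,-22,confirmation
florfenicol amine,milk,2.5,3.8,94,-13,confirmation
sulfanilamide,muscle,6.6,8.9,74,-35,confirmation
sulfanilamide,milk,5.8,12,66,-21,confirmation
desacetylcephapirin,muscle,7.6,7.3,76,-1,confirmation
desacetylcephapirin,milk,5.9,6.0,91,-21,confirmation
amoxicillin,muscle,4.5,6.3,64,-1,confirmation
amoxicillin,milk,5.8,5.8,89,-10,confirmation
sulfadiazine,muscle,5.1,8.2,86,-18,confirmation
sulfadiazine,milk,4.8,8.6,74,-16,confirmation
sulfathiazole,muscle,5.2,8.0,83,-6,confirmation
sulfathiazole,milk,5.2,8.3,71,-15,confirmation
cephapirin,muscle,6.9,7.8,75,1,confirmation
cephapirin,milk,12,12,94,-5,confirmation
sulfapyridine,muscle,4.6,7.2,85,13,confirmation
sulfapyridine,milk,5.8,9.5,67,-13,confirmation
tildipirosin,muscle,6.2,10,72,-8,confirmation
tildipirosin,milk,6.0,20,87,5,confirmation
cefquinome,muscle,6.1,7.2,97,-4,confirmation
cefquinome,milk,11,19,78,-16,screening_only
sulfamerazine,muscle,3.8,5.9,89,11,confirmation
sulfamerazine,milk,6.7,8.7,70,-13,confirmation
cefacetrile,muscle,12,13,80,-26,confirmation
cefacetrile,milk,22,27,92,-5,screening_only
cefalonium,muscle,6.7,7.3,78,3,confirmation
cefalonium,milk,8.7,8.7,93,-6,confirmation
lincomycin,muscle,4.3,7.2,83,-12,confirmation
lincomycin,milk,2.3,4.4,92,30,confirmation
epitetracycline,muscle,6.2,9.2,66,22,confirmation
epitetracycline,milk,4.7,7.6,96,5,confirmation
trimethoprim,muscle,3.4,7.8,90,-3,confirmation
trimethoprim,milk,2.7,4.9,94,4,confirmation
thiamphenicol,muscle,10,11,87,-13,confirmation
thiamphenicol,milk,13,13,92,-13,confirmation
tulathromycin marker,muscle,5.6,8.6,81,-13,confirmation
tulathromycin marker,milk,8.7,26,81,-18,confirmation
marbofloxacin,muscle,6.1,7.0,87,-27,confirmation
marbofloxacin,milk,4.3,4.9,96,-11,confirmation
sulfamethazine,muscle,4.1,7.2,85,-1,confirmation
sulfamethazine,milk,7.8,14,68,-13,confirmation
epioxytetracycline,muscle,8.8,13,62,40,confirmation
epioxytetracycline,milk,13,15,90,-3,confirmation
norfloxacin,milk,7.0,8.0,94,3,confirmation
tetracycline,muscle,6.3,9.4,71,27,confirmation
tetracycline,milk,4.5,5.0,91,40,confirmation
cefalexin,muscle,6.2,8.4,64,1,confirmation
cefalexin,milk,6.2,6.7,90,-7,confirmation
oxytetracycline,muscle,6.7,8.1,63,10,confirmation
oxytetracycline,milk,4.4,5.2,90,1,confirmation
ciprofloxacin,muscle,7.5,8.4,81,-25,confirmation
ciprofloxacin,milk,6.1,7.5,95,-10,confirmation
enrofloxacin,muscle,4.7,6.6,93,-16,confirmation
enrofloxacin,milk,4.1,5.9,99,-1,confirmation
tulathromycin,muscle,8.3,16,69,10,confirmation
tulathromycin,milk,7.5,13,94,5,confirmation
danofloxacin,muscle,5.7,7.2,90,-17,confirmation
danofloxacin,milk,4.2,5.0,97,3,confirmation
cefazolin,muscle,8.4,9.0,83,-8,confirmation
cefazolin,milk,14,14,94,-11,confirmation
sulfamethoxazole,muscle,7.7,9.7,88,-16,confirmation
sulfamethoxazole,milk,6.7,6.7,84,-24,confirmation
difloxacin,muscle,5.0,7.4,93,-15,confirmation
difloxacin,milk,3.3,4.2,96,-13,confirmation
ampicillin,muscle,6.6,8.0,68,-2,confirmation
ampicillin,milk,9.4,10,88,-10,confirmation
sulfamonomethoxine,muscle,4.6,7.4,86,0,confirmation
sulfamonomethoxine,milk,6.4,9.9,78,-19,confirmation
florfenicol,muscle,9.8,16,90,-17,confirmation
florfenicol,milk,13,13,94,-28,confirmation
cefoperazone,muscle,6.8,8.4,85,-13,confirmation
cefoperazone,milk,16,18,103,-25,confirmation
sarafloxacin,muscle,5.8,7.4,86,-26,confirmation
sarafloxacin,milk,4.8,6.6,99,-22,confirmation
epichlortetracycline,muscle,9.3,13,71,65,confirmation
epichlortetracycline,milk,7.4,11,100,22,confirmation
neospiramycin,muscle,7.8,16,67,12,confirmation
neospiramycin,milk,7.3,12,86,13,confirmation
chlortetracycline,muscle,5.8,7.7,69,47,confirmation
chlortetracycline,milk,5.7,7.2,92,48,confirmation
spiramycin,muscle,8.4,17,74,20,confirmation
spiramycin,milk,4.5,7.6,91,21,confirmation
sulfadimethoxine,muscle,4.5,8.1,88,-12,confirmation
sulfadimethoxine,milk,3.9,3.9,90,-29,confirmation
sulfaquinoxaline,muscle,6.1,7.7,86,-26,confirmation
sulfaquinoxaline,milk,4.6,4.8,91,-38,confirmation
oxolinic acid,muscle,4.9,6.7,97,4,confirmation
oxolinic acid,milk,2.6,6.6,96,-3,confirmation
ceftiofur,muscle,7.5,9.7,72,-21,confirmation
ceftiofur,milk,6.7,7.1,95,-24,confirmation
gamithromycin,muscle,5.6,7.1,94,55,confirmation
gamithromycin,milk,3.2,4.8,98,26,confirmation
tilmicosin,muscle,6.9,10,88,49,confirmation
tilmicosin,milk,3.2,4.4,95,38,confirmation
doxycycline,muscle,7.0,9.5,69,1,confirmation
doxycycline,milk,6.6,7.4,95,10,confirmation
nalidixic acid,milk,3.6,6.0,94,-3,confirmation
penicillin G,muscle,7.9,9.0,85,-21,confirmation
penicillin G,milk,12,13,92,37,confirmation
tiamulin,muscle,9.3,13,88,-21,confirmation
tiamulin,milk,2.5,4.1,98,-5,confirmation
flumequine,muscle,4.3,7.3,95,-3,confirmation
flumequine,milk,2.9,4.5,95,52,confirmation
tylosin A,muscle,7.7,15,85,29,confirmation
tylosin A,milk,2.5,4.8,96,54,confirmation
erythromycin A,muscle,4.9,8.6,89,-27,confirmation
erythromycin A,milk,4.7,12,67,-21,confirmation
3-O-acetyltylosin,muscle,9.3,16,88,42,confirmation
3-O-acetyltylosin,milk,3.7,5.0,95,53,confirmation
oxacillin,muscle,6.0,11,83,-29,confirmation
oxacillin,milk,8.0,8.5,100,1,confirmation
penicillin V,muscle,7.9,11,85,-28,confirmation
penicillin V,milk,7.5,7.7,99,6,confirmation
cloxacillin,muscle,8.2,11,84,-27,confirmation
cloxacillin,milk,9.8,12,110,-25,confirmation
valnemulin,muscle,19,31,75,-26,screening_only
valnemulin,milk,2.7,5.4,108,55,confirmation
dicloxacillin,muscle,6.7,10,81,-25,confirmation
dicloxacillin,milk,13,13,99,-10,confirmation
nafcillin,muscle,5.0,8.2,84,-7,confirmation
nafcillin,milk,5.0,5.4,99,-19,confirmation
tylvalosin,muscle,9.0,19,93,50,confirmation
tylvalosin,milk,5.4,6.9,101,90,confirmation
rifaximin,muscle,9.0,12,91,33,confirmation
rifaximin,milk,4.8,9.6,98,7,confirmation
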