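sample_code,year,organizer,matrix,analyte,found_orbitrap,found_qqq,consensus,range_low,range_high
MI1432-A1,2014,Test Veritas,milk,sulfamethazine,144,96,103,57,150
MI1432-A2,2014,Test Veritas,milk,amoxicillin,5,ND,Not assigned,,
M1435-A1,2014,Test Veritas,pig muscle,sulfamethazine,88,75,69,36,102
M1435-A1,2014,Test Veritas,pig muscle,sulfadimethoxine,32,23,27,12,42
M1433-A2,2014,Test Veritas,turkey muscle,ciprofloxacin,5.5,5,5.6,3.2,8.1
M1433-A2,2014,Test Veritas,turkey muscle,enrofloxacin,173,152,160,92,227
MI1532-A1,2015,Test Veritas,milk,amoxicillin,16,ND,14,5.6,22
MI1532-A2,2015,Test Veritas,milk,sulfamethazine,165,131,134,75,191
MI1623-A1,2016,Test Veritas,milk,flumequine,91,111,88,47,129
MI1623-A2,2016,Test Veritas,milk,oxytetracycline,93,55,91,49,132
MI1715-A2,2017,Test Veritas,milk,danofloxacin,91,80,74,39,109
484 (material C),2018,RIKILT,bovine muscle,marbofloxacin,178,193,170,100,240
484 (material C),2018,RIKILT,bovine muscle,oxytetracycline,89,79,106,59,152
334,2019,RIKILT,bovine muscle,ciprofloxacin,10,10,NA,,
334,2019,RIKILT,bovine muscle,enrofloxacin,82,84,NA,,
544,2019,RIKILT,bovine muscle,tylosin A,54,87,NA,,
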