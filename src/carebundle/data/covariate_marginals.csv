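country,variable,level,probability
Wales,age_band,60-64,0.035
Wales,age_band,65-69,0.058
Wales,age_band,70-74,0.098
Wales,age_band,75-79,0.16
Wales,age_band,80-84,0.242
Wales,age_band,85-89,0.242
Wales,age_band,90+,0.165
Wales,sex,female,0.722
Wales,sex,male,0.278
Wales,admission_source,hospital,0.045
Wales,admission_source,nursing_home,0.154
Wales,admission_source,residential_home,0.786
Wales,admission_source,other,0.016
Wales,asa,1,0.027
Wales,asa,2,0.308
Wales,asa,3,0.538
Wales,asa,4,0.121
Wales,asa,5,0.006
Wales,mobility,full,0.352
Wales,mobility,outdoor,0.254
Wales,mobility,indoor,0.373
Wales,mobility,none,0.02
Wales,fracture,intracapsular,0.579
Wales,fracture,extracapsular,0.421
England,age_band,60-64,0.032
England,age_band,65-69,0.054
England,age_band,70-74,0.092
England,age_band,75-79,0.155
England,age_band,80-84,0.242
England,age_band,85-89,0.247
England,age_band,90+,0.178
England,sex,female,0.731
England,sex,male,0.269
England,admission_source,hospital,0.035
England,admission_source,nursing_home,0.174
England,admission_source,residential_home,0.779
England,admission_source,other,0.012
England,asa,1,0.026
England,asa,2,0.309
England,asa,3,0.547
England,asa,4,0.114
England,asa,5,0.004
England,mobility,full,0.358
England,mobility,outdoor,0.263
England,mobility,indoor,0.357
England,mobility,none,0.022
England,fracture,intracapsular,0.593
England,fracture,extracapsular,0.407
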