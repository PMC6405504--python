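species,worker_mm,male_mm,queen_mm,genus,source,ssdi_printed,mean_printed
Austroplebeia australis,1.31,1.31,1.43,Austroplebeia,d,0.091,1.37
Austroplebeia cassiae,1.36,1.37,1.45,Austroplebeia,d,0.058,1.41
Austroplebeia cincta,1.11,1.15,1.23,Austroplebeia,d,0.070,1.19
Austroplebeia essingtoni,1.10,1.13,1.17,Austroplebeia,d,0.035,1.15
Austroplebeia magna,1.33,1.35,1.39,Austroplebeia,d,0.030,1.37
Axestotrigona ferruginea,1.925,2.00,2.32,Axestotrigona,c,0.160,2.16
Bombus terrestris,4.77,7.76,7.86,Bombus,k,0.013,7.81
Cephalotrigona capitata,2.88,2.63,3.75,Cephalotrigona,b,0.425,3.19
Cephalotrigona zexmeniae,2.081,1.925,2.468,Cephalotrigona,m,0.282,2.196
Euglossa imperialis,,5.38,5.61,Euglossa,n,0.043,5.50
Exaerete smaragdina,,7.05,8.11,Exaerete,n,0.150,7.58
Frieseomelitta nigra,1.227,1.307,1.352,Frieseomelitta,m,0.034,1.329
Lepidotrigona ventralis,1.44,1.48,2.05,Lepidotrigona,f,0.385,1.765
Lestrimelitta limao,2.00,2.00,2.75,Lestrimelitta,b,0.375,2.375
Lestrimelitta niitkib,1.493,1.584,1.89,Lestrimelitta,m,0.191,1.737
Melipona beecheii,2.528,2.556,2.158,Melipona,l,-0.155,2.357
Melipona bicolor,3.875,4.00,3.25,Melipona,b,-0.188,3.625
Melipona colimana,2.894,2.985,2.699,Melipona,m,-0.095,2.842
Melipona eburnea,4.89,4.708,4.409,Melipona,e,-0.063,4.558
Melipona fallax,3.43,3.53,3.48,Melipona,h,-0.014,3.51
Melipona favosa,2.633,2.675,1.968,Melipona,i,-0.264,2.321
Melipona fuliginosa,3.68,3.92,3.33,Melipona,h,-0.151,3.625
Melipona marginata,2.299,2.307,1.86,Melipona,i,-0.193,2.083
Melipona quadrifasciata,2.888,2.884,2.61,Melipona,i,-0.095,2.747
Melipona rufiventris,3.75,4.00,3.25,Melipona,a,-0.188,3.63
Melipona scutellaris,3.01,2.87,2.71,Melipona,j,-0.056,2.79
Melipona yucatanica,2.235,2.245,1.97,Melipona,m,-0.11,2.107
Nannotrigona perilampoides,1.309,1.224,1.453,Nannotrigona,m,0.187,1.338
Oxytrigona tataira,1.526,1.522,2.16,Oxytrigona,i,0.424,1.841
Partamona bilineata,1.589,1.561,1.655,Partamona,m,0.060,1.608
Plebeia frontalis,1.02,1.018,0.993,Plebeia,m,-0.024,1.00
Scaptotrigona mexicana,1.453,1.524,1.82,Scaptotrigona,m,0.194,1.672
Scaptotrigona pectoralis,1.613,1.582,1.831,Scaptotrigona,m,0.157,1.706
Scaura latitarsis,1.25,1.25,1.50,Scaura,b,0.200,1.375
Scaura longula,1.50,1.50,1.66,Scaura,b,0.107,1.58
Schwarziana quadripunctata,1.748,1.865,2.039,Schwarziana,i,0.093,1.952
Tetragonisca angustula,1.019,1.061,1.886,Tetragonisca,e,0.777,1.473
Trichotrigona extranea,NA,1.48,1.25,Trichotrigona,g,-0.155,1.365
Trigona amalthea,2.218,1.982,2.729,Trigona,e,0.376,2.355
Trigona chanchamayoensis,1.88,2.00,2.75,Trigona,b,0.375,2.375
Trigona corvina,2.13,2.25,2.75,Trigona,b,0.222,2.50
Trigona fulviventris,1.429,1.606,1.871,Trigona,m,0.165,1.738
Trigona nigerrima,2.38,2.50,2.75,Trigona,b,0.100,2.625
Trigona pallens,1.416,1.722,2.047,Trigona,i,0.188,1.884
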