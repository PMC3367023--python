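site,taxon,reads_genus,reads_phylum,reads_tetra,proteins,sequence_mb,pct_of_site,est_genome_mb,depth,coverage_pct
site1,Aquificae,11287,40875,44806,18005,50.1,60.7,1.6,31.28,100.0
site1,Crenarchaeota,4854,10599,11065,6656,12.3,14.9,2,6.13,99.8
site1,Deinococcus,1643,1745,1881,1718,2.0,2.4,2.1,0.96,61.6
site1,Proteobacteria,2092,3455,3743,3801,4.2,5.1,5,0.84,56.9
site2,Aquificae,6694,24489,27138,10649,24.8,31.4,1.6,15.49,100.0
site2,Crenarchaeota,5951,14710,15274,7989,13.6,17.2,2,6.80,99.9
site2,Deinococcus,2054,2256,2686,2098,2.4,3.0,2.1,1.13,67.6
site2,Proteobacteria,2780,4799,5279,4709,4.8,6.1,5,0.96,61.6
site3,Actinobacteria-Planctomycetes,0,895,28374,11239,33.4,38.2,5,6.67,99.9
site3,Aquificae,287,3118,3780,3337,4.4,5.0,1.6,2.73,93.5
site3,Chloroflexi,1051,1904,1950,1560,2.3,2.6,5.8,0.39,32.4
site3,Deinococcus,19526,20371,20778,8958,23.1,26.4,2.1,10.98,100.0
site3,Proteobacteria,344,2392,2557,1711,3.0,3.4,5,0.60,44.9
site4,Chlorobi,613,3086,5263,3135,5.1,3.9,3.3,1.54,78.5
site4,Chloroflexi,27869,30089,30855,19487,29.6,23.0,5.8,5.11,99.4
site4,Cyanobacteria,26458,30674,31497,15381,29.8,23.1,3,9.94,100.0
site4,Deinococcus,940,1329,1614,1383,1.6,1.2,2.1,0.74,52.4
site4,Planctomycetes,0,471,3185,2332,3.1,2.4,5,0.61,45.7
site4,Proteobacteria,6883,11636,15752,7922,15.0,11.6,5,3.00,95.0
site5,Chlorobi,291,1418,1883,1508,1.8,1.9,3.3,0.54,42.0
site5,Chloroflexi,24638,26850,27462,17247,25.9,27.8,5.8,4.47,98.9
site5,Cyanobacteria,9120,10828,11217,7382,10.6,11.4,3,3.54,97.1
site5,Deinococcus,1339,1790,2207,2128,2.0,2.2,2.1,0.97,61.9
site5,Planctomycetes,0,360,5539,4021,5.2,5.6,5,1.04,64.7
site5,Proteobacteria,6778,9734,10951,7552,10.3,11.0,5,2.06,87.3
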