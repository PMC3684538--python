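family,e0_level,age_group_start,p5x
synthetic-general,50,15,0.975
synthetic-general,50,20,0.968
synthetic-general,50,25,0.962
synthetic-general,50,30,0.956
synthetic-general,50,35,0.950
synthetic-general,50,40,0.942
synthetic-general,50,45,0.930
synthetic-general,50,50,0.910
synthetic-general,60,15,0.985
synthetic-general,60,20,0.981
synthetic-general,60,25,0.977
synthetic-general,60,30,0.973
synthetic-general,60,35,0.968
synthetic-general,60,40,0.961
synthetic-general,60,45,0.950
synthetic-general,60,50,0.932
synthetic-general,70,15,0.992
synthetic-general,70,20,0.990
synthetic-general,70,25,0.988
synthetic-general,70,30,0.986
synthetic-general,70,35,0.983
synthetic-general,70,40,0.978
synthetic-general,70,45,0.968
synthetic-general,70,50,0.952
synthetic-general,80,15,0.997
synthetic-general,80,20,0.996
synthetic-general,80,25,0.995
synthetic-general,80,30,0.994
synthetic-general,80,35,0.992
synthetic-general,80,40,0.988
synthetic-general,80,45,0.981
synthetic-general,80,50,0.970
synthetic-south-asian,50,15,0.970
synthetic-south-asian,50,20,0.963
synthetic-south-asian,50,25,0.957
synthetic-south-asian,50,30,0.951
synthetic-south-asian,50,35,0.945
synthetic-south-asian,50,40,0.936
synthetic-south-asian,50,45,0.922
synthetic-south-asian,50,50,0.900
synthetic-south-asian,60,15,0.982
synthetic-south-asian,60,20,0.978
synthetic-south-asian,60,25,0.974
synthetic-south-asian,60,30,0.969
synthetic-south-asian,60,35,0.964
synthetic-south-asian,60,40,0.956
synthetic-south-asian,60,45,0.944
synthetic-south-asian,60,50,0.925
synthetic-south-asian,70,15,0.991
synthetic-south-asian,70,20,0.989
synthetic-south-asian,70,25,0.986
synthetic-south-asian,70,30,0.984
synthetic-south-asian,70,35,0.980
synthetic-south-asian,70,40,0.974
synthetic-south-asian,70,45,0.963
synthetic-south-asian,70,50,0.946
synthetic-south-asian,80,15,0.996
synthetic-south-asian,80,20,0.995
synthetic-south-asian,80,25,0.994
synthetic-south-asian,80,30,0.993
synthetic-south-asian,80,35,0.990
synthetic-south-asian,80,40,0.986
synthetic-south-asian,80,45,0.978
synthetic-south-asian,80,50,0.966
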