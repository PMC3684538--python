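year,baseline_users,baseline_contribution,pre_existing_users,existing_users,maintain_users,increase_users,new_users,new_adopters,situation,counting_fraction,dropped_continuers,total_users_in_cpr,total_pct_contribution,pct_point_increase
2005,313.5415595,5.58647273e-05,175.1401852,0,138.4013744,59.08833632,275.8236183,61.78449049,3,0.716,0,372.6298959,0.006458432864,0.0008719601343
2006,313.5415595,5.58647273e-05,134.1096289,78.81372163,159.7065453,79.41526014,354.5324113,79.41526014,1,0.6744709308,14.72340104,452.045156,0.007621459733,0.002034987003
2007,313.5415595,5.58647273e-05,84.9750073,156.8470111,210.2231376,104.628252,467.0904109,104.628252,1,0.6740694785,19.58534453,556.6734081,0.00912985123,0.0035433785
2008,313.5415595,5.58647273e-05,70.75318379,233.9370825,251.9831418,140.4168352,626.8608716,140.4168352,1,0.6259761851,56.43240706,697.0902433,0.01112139112,0.005534918394
2009,313.5415595,5.58647273e-05,56.2931125,319.5632573,321.2338735,188.0384638,839.4574275,188.0384638,1,0.606668451,91.77918087,885.1287071,0.01373673189,0.008150259162
2010,313.5415595,5.58647273e-05,50.53765371,431.9700917,402.6209617,274.591469,1225.854772,274.591469,1,0.5524409955,200.4995862,1159.720176,0.01750802241,0.01192154968
2011,313.5415595,5.58647273e-05,45.00863134,585.8432532,528.8682914,333.7730756,1490.058373,333.7730756,1,0.578931257,204.2404283,1493.493252,0.0219327976,0.01634632487
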