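year,total_users,lapm_users,short_term_users,users_served,adopters_served,adopters_increasing_cpr
2005,26244,14105,12139,17617,3945,2489
2006,33525,21371,12154,20387,4566,3842
2007,46255,31636,14619,26273,5884,5005
2008,55550,44109,11442,25708,5757,4676
2009,83317,73427,9890,41861,9375,8085
2010,141038,123768,17270,73315,16419,14793
2011,197860,175283,22577,85573,19164,17005
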