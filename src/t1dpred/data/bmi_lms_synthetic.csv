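gender,age,L,M,S
female,1.0,-1.4872,14.574,0.0772
female,1.5,-1.4706,14.856,0.0784
female,2.0,-1.4528,15.106,0.0795
female,2.5,-1.4339,15.329,0.0806
female,3.0,-1.414,15.53,0.0818
female,3.5,-1.3933,15.713,0.0829
female,4.0,-1.3721,15.882,0.084
female,4.5,-1.3507,16.043,0.0851
female,5.0,-1.3293,16.197,0.0862
female,5.5,-1.3085,16.349,0.0874
female,6.0,-1.2885,16.503,0.0885
female,6.5,-1.2697,16.661,0.0896
female,7.0,-1.2525,16.828,0.0908
female,7.5,-1.2372,17.006,0.0919
female,8.0,-1.2242,17.198,0.093
female,8.5,-1.2138,17.409,0.0941
female,9.0,-1.2062,17.64,0.0952
female,9.5,-1.2016,17.893,0.0964
female,10.0,-1.2,18.17,0.0975
female,10.5,-1.2016,18.469,0.0986
female,11.0,-1.2062,18.792,0.0998
female,11.5,-1.2138,19.134,0.1009
female,12.0,-1.2242,19.492,0.102
female,12.5,-1.2372,19.861,0.1031
female,13.0,-1.2525,20.235,0.1042
female,13.5,-1.2697,20.608,0.1054
female,14.0,-1.2885,20.973,0.1065
female,14.5,-1.3085,21.324,0.1076
female,15.0,-1.3293,21.657,0.1088
female,15.5,-1.3507,21.966,0.1099
female,16.0,-1.3721,22.25,0.111
female,16.5,-1.3933,22.507,0.1121
female,17.0,-1.414,22.736,0.1132
female,17.5,-1.4339,22.938,0.1144
female,18.0,-1.4528,23.115,0.1155
female,18.5,-1.4706,23.269,0.1166
female,19.0,-1.4872,23.401,0.1178
female,19.5,-1.5024,23.513,0.1189
female,20.0,-1.5162,23.609,0.12
male,1.0,-1.4872,14.874,0.0772
male,1.5,-1.4706,15.156,0.0784
male,2.0,-1.4528,15.406,0.0795
male,2.5,-1.4339,15.629,0.0806
male,3.0,-1.414,15.83,0.0818
male,3.5,-1.3933,16.013,0.0829
male,4.0,-1.3721,16.182,0.084
male,4.5,-1.3507,16.343,0.0851
male,5.0,-1.3293,16.497,0.0862
male,5.5,-1.3085,16.649,0.0874
male,6.0,-1.2885,16.803,0.0885
male,6.5,-1.2697,16.961,0.0896
male,7.0,-1.2525,17.128,0.0908
male,7.5,-1.2372,17.306,0.0919
male,8.0,-1.2242,17.498,0.093
male,8.5,-1.2138,17.709,0.0941
male,9.0,-1.2062,17.94,0.0952
male,9.5,-1.2016,18.193,0.0964
male,10.0,-1.2,18.47,0.0975
male,10.5,-1.2016,18.769,0.0986
male,11.0,-1.2062,19.092,0.0998
male,11.5,-1.2138,19.434,0.1009
male,12.0,-1.2242,19.792,0.102
male,12.5,-1.2372,20.161,0.1031
male,13.0,-1.2525,20.535,0.1042
male,13.5,-1.2697,20.908,0.1054
male,14.0,-1.2885,21.273,0.1065
male,14.5,-1.3085,21.624,0.1076
male,15.0,-1.3293,21.957,0.1088
male,15.5,-1.3507,22.266,0.1099
male,16.0,-1.3721,22.55,0.111
male,16.5,-1.3933,22.807,0.1121
male,17.0,-1.414,23.036,0.1132
male,17.5,-1.4339,23.238,0.1144
male,18.0,-1.4528,23.415,0.1155
male,18.5,-1.4706,23.569,0.1166
male,19.0,-1.4872,23.701,0.1178
male,19.5,-1.5024,23.813,0.1189
male,20.0,-1.5162,23.909,0.12
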