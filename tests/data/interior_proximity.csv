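group,stimulus,Joyful,Relaxed,Surprise,Dependent,Boring,Fear,Contempt,Digust
young,Nordic,2.7569,1.9480,1.9019,1.9066,2.0574,1.6833,2.3165,2.4228
young,Franch,3.1260,2.2304,2.3165,1.5624,1.6211,1.5254,2.2892,2.3668
young,American,2.6503,1.8827,1.7958,1.9129,2.1413,1.7946,2.4577,2.5647
young,pastoralism,3.6064,2.9491,2.6160,2.1084,1.7971,0.8989,1.4373,1.4545
young,Modern,3.0242,2.2907,2.1474,1.6404,1.7674,1.5084,2.2953,2.3686
young,New Chinese,3.2060,2.3581,2.3408,1.6718,1.6312,1.3478,2.0772,2.1469
young-man,Nordic,3.0023,2.1514,2.1048,1.7277,1.8281,1.4753,2.2229,2.2994
young-man,Franch,3.4367,2.5285,2.5708,1.5131,1.3836,1.2439,2.0686,2.1111
young-man,American,2.9488,2.1530,2.0631,1.7138,1.8570,1.5431,2.2993,2.3791
young-man,pastoralism,3.4839,2.7840,2.4935,2.0359,1.7989,0.9673,1.5694,1.5997
young-man,Modern,3.2441,2.5037,2.3248,1.6095,1.6141,1.2797,2.1102,2.1594
young-man,New Chinese,3.3141,2.4950,2.3936,1.6864,1.6015,1.1952,1.9733,2.0218
young-woman,Nordic,2.4303,1.6882,1.6504,2.1663,2.3689,1.9748,2.4745,2.6149
young-woman,Franch,2.7223,1.8525,2.0167,1.7321,1.9843,1.9297,2.6230,2.7360
young-woman,American,2.2536,1.5238,1.4605,2.2148,2.5268,2.1502,2.7071,2.8433
young-woman,pastoralism,3.7324,3.1371,2.7455,2.1965,1.8114,0.8576,1.2998,1.3028
young-woman,Modern,2.7385,2.0189,1.9352,1.7367,2.0016,1.8213,2.5588,2.6579
young-woman,New Chinese,3.0685,2.1771,2.2854,1.6753,1.6928,1.5528,2.2254,2.3198
elderly,Nordic,2.6421,2.0189,1.6926,2.0678,2.2631,1.7221,2.3389,2.4419
elderly,Franch,2.9522,2.2222,2.1035,1.9340,1.9330,1.5046,2.0607,2.1673
elderly,American,3.2097,2.2267,2.4763,1.7841,1.6162,1.4959,2.0157,2.1260
elderly,pastoralism,2.5591,1.8072,1.6943,2.1754,2.3260,1.8140,2.3091,2.4381
elderly,Modern,2.9620,2.3448,2.1018,1.8626,1.8948,1.5006,2.1205,2.2179
elderly,New Chinese,3.6725,2.7621,2.7876,1.5941,1.2648,1.0600,1.8608,1.8796
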