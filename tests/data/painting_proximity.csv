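group,stimulus,Joyful,Relaxed,Surprise,Dependent,Boring,Fear,Contempt,Digust
young,Renaissance,,,2.2467,1.7088,1.7156,1.3146,2.0792,2.1408
young,Baroque,,,2.3295,1.7126,1.6642,1.4257,2.0899,2.1757
young,Romanticism,,,2.1190,1.5635,1.7639,1.4827,2.3695,2.4241
young,Impressionistic,,,,1.7964,2.1225,1.8448,2.6148,2.7066
young,Post-impressionistic,,,2.1972,1.7855,1.7897,1.4356,2.0977,2.1846
young,Contemporary art,,,2.7424,1.7177,,,1.7584,1.7919
young,modernism,,,2.2009,2.2773,2.1164,1.4965,,1.8648
young,abstractionism,,,2.2067,1.9568,1.8816,1.3302,1.8931,1.9815
young-man,Renaissance,,,2.2827,1.7141,1.6924,1.3015,2.0485,2.1116
young-man,Baroque,,,2.3898,1.7501,1.6400,1.3795,2.0033,2.0904
young-man,Romanticism,,,2.3127,1.6615,1.6495,1.2097,2.0460,2.0880
young-man,Impressionistic,,,,1.5777,1.8284,1.5158,2.4238,2.4760
young-man,Post-impressionistic,,,2.4834,1.7613,1.5818,1.1553,1.8483,1.9025
young-man,Contemporary art,,,2.6197,1.6639,,,1.8477,1.8751
young-man,modernism,,,2.3018,1.9690,1.8322,1.2721,1.8035,1.8901
young-man,abstractionism,,,2.4051,1.8932,1.7324,1.0657,,1.7938
young-woman,Renaissance,,,2.2942,1.7213,1.6919,1.2132,2.0040,2.0524
young-woman,Baroque,,,2.3805,1.6868,1.6097,1.3234,2.0329,2.1030
young-woman,Romanticism,,,1.9255,1.5443,1.9984,1.8815,2.8072,2.8740
young-woman,Impressionistic,,,,2.1441,2.5378,2.2943,2.9166,3.0506
young-woman,Post-impressionistic,,,1.9262,1.8971,2.0437,1.7177,2.3362,2.4481
young-woman,Contemporary art,,,2.9120,1.6776,,,1.7463,1.7594
young-woman,modernism,,,2.1363,2.6941,2.5103,1.8423,,1.9176
young-woman,abstractionism,,,1.9700,2.0945,2.1192,1.6869,2.1222,2.2588
elderly,Renaissance,,,2.3360,1.6228,1.6198,1.4450,,2.2536
elderly,Baroque,,,2.3346,1.4832,,1.6533,2.4431,2.5234
elderly,Romanticism,,,2.0758,1.6317,1.8334,1.6328,2.4252,2.5052
elderly,Impressionistic,,,,2.3103,2.7643,2.3948,3.0346,3.1606
elderly,Post-impressionistic,,,1.2952,2.2124,2.5938,2.0595,2.7375,2.8387
elderly,Contemporary art,,,2.2594,1.5858,1.6643,,2.2682,2.3399
elderly,modernism,,,1.5666,2.1103,2.3816,1.9518,2.5513,2.6714
elderly,abstractionism,,,1.7143,2.1225,2.2801,1.7453,2.2924,2.4085
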