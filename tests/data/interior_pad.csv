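group,stimulus,P,A,D,emotion
young,Nordic,0.5524,0.2119,0.1214,Joyful
young,Franch,0.3810,-0.1595,,Mild
young,American,0.6929,0.2429,0.0881,Joyful
young,pastoralism,-0.4595,0.2667,0.1214,Digust
young,Modern,0.4190,0.0262,,Dependent
young,New Chinese,0.1881,-0.0452,,Mild
young-man,Nordic,0.3750,0.1083,,Dependent
young-man,Franch,0.0542,,,Mild
young-man,American,0.4542,0.1000,,Dependent
young-man,pastoralism,,0.2708,0.0958,Digust
young-man,Modern,0.1750,0.0042,,Dependent
young-man,New Chinese,0.0500,0.0167,,Dependent
young-woman,Nordic,0.7889,0.3500,,Joyful
young-woman,Franch,0.8167,,,Relaxed
young-woman,American,1.0111,0.4333,,Joyful
young-woman,pastoralism,,0.2611,,Digust
young-woman,Modern,0.7444,0.0556,,Dependent
young-woman,New Chinese,0.3722,,,Relaxed
elderly,Nordic,0.5833,0.4583,0.1417,Joyful
elderly,Franch,0.3000,0.1583,0.1917,Joyful
elderly,American,0.1750,,0.1917,Relaxed
elderly,pastoralism,0.6083,0.4333,0.2917,Joyful
elderly,Modern,0.3333,0.1333,0.1250,Joyful
elderly,New Chinese,,,,Boring
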