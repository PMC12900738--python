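group,stimulus,P,A,D,emotion
young,Renaissance,0.1963,0.0786,-0.0333,Dependent
young,Baroque,0.2333,-0.0762,0.0595,Relaxed
young,Romanticism,0.4429,0.0690,-0.1881,Dependent
young,Impressionistic,0.8000,0.2071,-0.0571,Dependent
young,Post-impressionistic,0.2743,0.0619,0.0738,Joyful
young,Contemporary art,-0.2500,-0.1833,-0.0143,Boring
young,modernism,0.0524,0.2976,0.4810,Joyful
young,abstractionism,0.1071,0.2048,0.1690,Joyful
young-man,Renaissance,0.1667,0.0542,-0.0167,Dependent
young-man,Baroque,0.1500,-0.0875,0.0958,Relaxed
young-man,Romanticism,0.1125,0.0792,-0.1042,Dependent
young-man,Impressionistic,0.4958,0.1292,-0.2167,Dependent
young-man,Post-impressionistic,-0.0583,-0.0125,0.0250,Contempt
young-man,Contemporary art,-0.1542,-0.0958,-0.0792,Boring
young-man,modernism,0.0125,0.1667,0.1875,Joyful
young-man,abstractionism,-0.1333,0.1875,0.0417,Digust
young-woman,Renaissance,0.0980,0.1111,-0.0556,Dependent
young-woman,Baroque,0.1432,-0.0611,0.0111,Relaxed
young-woman,Romanticism,0.8833,0.0556,-0.3000,Dependent
young-woman,Impressionistic,1.2056,0.3111,0.1556,Joyful
young-woman,Post-impressionistic,0.5778,0.1611,0.1389,Joyful
young-woman,Contemporary art,-0.3667,-0.3000,-0.0722,Boring
young-woman,modernism,0.1056,0.4722,0.8722,Joyful
young-woman,abstractionism,0.4278,0.2278,0.3389,Joyful
elderly,Renaissance,0.2833,-0.1167,-0.0167,Mild
elderly,Baroque,0.5083,-0.2583,-0.1083,Mild
elderly,Romanticism,0.5583,0.0167,-0.0833,Dependent
elderly,Impressionistic,1.3083,0.5750,0.1250,Joyful
elderly,Post-impressionistic,0.9583,0.6750,0.0583,Joyful
elderly,Contemporary art,0.3667,-0.0750,-0.0750,Mild
elderly,modernism,0.8250,0.4250,0.1750,Joyful
elderly,abstractionism,0.5667,0.4417,0.2250,Joyful
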