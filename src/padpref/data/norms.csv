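label,PN,AN,DN
Joyful,2.77,1.21,1.42
Relaxed,2.19,-0.66,1.05
Surprise,1.72,1.71,0.22
Dependent,0.39,-0.81,-1.48
Boring,-0.53,-1.25,-0.84
Fear,-0.95,0.32,-0.63
Contempt,-1.58,0.32,1.02
Disgust,-1.8,0.4,0.67
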