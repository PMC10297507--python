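age,sex,cp,trestbps,chol,fbs,restecg,thalach,exang,oldpeak,slope,ca,thal
40,1,1,97,539,1,2,198,0,0.2,2,1,2
65,0,0,157,281,1,2,142,0,2,1,4,3
55,0,1,180,408,0,2,119,0,3,0,0,1
70,1,3,118,208,1,2,153,0,4,1,0,0
40,0,3,153,409,0,1,186,1,2.4,0,2,0
32,0,2,127,245,1,2,192,0,1.8,1,4,3
70,0,1,142,160,0,2,188,0,0.6,0,2,1
59,1,3,157,481,0,1,117,1,0.9,2,3,1
62,1,2,151,490,1,1,146,0,1.2,0,4,3
63,0,0,129,505,1,0,189,1,1,1,1,3
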