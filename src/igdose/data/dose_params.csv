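modality,organ,form,y0,a,b,comment
CT,brain,EXP_DECAY,1.23,1.49E-02,,
CT,lung,EXP_DECAY,1.48,9.50E-03,,
CT,red_bone_marrow,EXP_DECAY,2.17,1.38E-02,,
kVPI,brain,LINEAR,2.0,-1.69E-02,,
kVPI,lung,LINEAR,2.05,-1.15E-02,,
kVPI,red_bone_marrow,LINEAR,1.95,-1.27E-02,,
MVPI,brain,LINEAR,4.32,-1.46E-02,,
MVPI,lung,LINEAR,4.46,-1.32E-02,,
MVPI,red_bone_marrow,LINEAR,4.07,-1.54E-02,,
kVCBCT,brain,QUADRATIC,29.02,-8.01E-01,0.0063,
kVCBCT,lung,LINEAR,3.61,-2.12E-02,,
kVCBCT,red_bone_marrow,LOG_AGE,33.55,-6.21E+00,-6.21E-02,age coefficient read as -6.21E-02: the printed -6.21 per year drives dose far negative at any adult age; -6.21E-02 keeps dose non-negative over pelvic circumferences 37-168 cm
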