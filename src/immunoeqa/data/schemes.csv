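scheme,family,name
SER,Serology,Serological typing of HLA class I
B27,Molecular typing,HLA-B27
B57,Molecular typing,HLA-B*57:01
CD,Molecular typing,Coeliac disease-related HLA
XM,Crossmatch,Cytotoxicity crossmatch
XMFC,Crossmatch,Cytometry crossmatch
ALO,Antibodies,Detection and specificity of anti-HLA antibodies
LOW,Molecular typing,Low-resolution HLA DNA typing
HI,Molecular typing,High-resolution HLA DNA typing
CHM,Chimerism,Chimerism
KIR,Molecular typing,KIR typing
HPA,Molecular typing,HPA typing
AHPA,Antibodies,Anti-HPA antibodies
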