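phoneme,vocalic,consonantal,high,back,low,anterior,coronal,round,tense,voice,continuant,nasal,strident,sonorant,lateral,delayed_release,distributed
a,1,0,0,1,1,1,0,0,0,1,1,0,0,1,0,0,0
ae,1,0,0,0,1,1,1,0,0,1,1,0,0,1,0,0,0
i,1,0,1,0,0,0,0,0,0,1,1,0,0,1,0,1,0
u,1,0,1,1,0,1,0,1,0,1,1,0,0,1,0,0,1
b,0,1,0,0,0,1,0,0,0,1,0,0,0,0,0,0,1
p,0,1,0,0,0,1,0,0,0,0,0,0,0,0,0,0,1
v,0,1,0,0,0,1,0,0,0,1,1,0,1,0,0,0,0
g,0,1,1,1,0,1,0,0,0,1,1,0,0,0,0,0,0
k,0,1,0,0,0,1,0,0,0,0,1,0,0,0,0,0,0
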