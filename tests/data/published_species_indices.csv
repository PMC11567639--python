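species,ur,ci,fc,nu,rfc,ri,cve
bambusa vulgaris,440,1.705,162,4,0.628,0.823,0.714
borassus aethiopum,406,1.574,211,2,0.818,0.670,0.429
elaeis guineensis,397,1.539,251,2,0.973,0.750,0.499
senna siamea,288,1.116,107,3,0.415,0.588,0.231
azadirachta indica,265,1.027,103,3,0.399,0.580,0.205
funtumia africana,199,0.771,138,2,0.535,0.525,0.138
rhipsalis baccifera,187,0.725,187,1,0.725,0.498,0.088
raphia palma-pinus,175,0.678,175,1,0.678,0.474,0.077
antiaris toxicaria,163,0.632,163,1,0.632,0.450,0.067
bridelia ferruginea,137,0.531,137,1,0.531,0.398,0.047
baphia nitida,130,0.504,130,1,0.504,0.384,0.042
cryptolepis nigrescens,127,0.492,127,1,0.492,0.378,0.040
andropogon gayanus,124,0.481,124,1,0.481,0.372,0.038
musa sapientum,121,0.469,121,1,0.469,0.366,0.037
anogeissus leiocarpa,110,0.426,110,1,0.426,0.344,0.030
gardenia ternifolia,101,0.391,101,1,0.391,0.326,0.026
leucaena leucocephala,91,0.353,91,1,0.353,0.306,0.021
eremospatha macrocarpa,83,0.322,83,1,0.322,0.290,0.017
avicennia germinans,81,0.314,81,1,0.314,0.286,0.016
cyperus papyrus,79,0.306,79,1,0.306,0.282,0.016
tectona grandis,74,0.287,74,1,0.287,0.272,0.014
cocos nucifera,73,0.283,73,1,0.283,0.270,0.013
tamarindus indica,68,0.264,68,1,0.264,0.260,0.012
diospyros mespiliformis,67,0.260,67,1,0.260,0.258,0.011
raphia hookeri,62,0.240,62,1,0.240,0.249,0.010
typha domingensis,61,0.236,61,1,0.236,0.247,0.009
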