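category,nur,ns,nur_minus_ns,nur_minus_1,iar
main pole,1183,12,1171,1182,0.991
main beam,730,6,724,729,0.993
wall lath,339,2,337,338,0.997
roof lath,539,4,535,538,0.994
binding material,518,4,514,517,0.994
thatch material,800,8,792,799,0.991
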