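category,species,fl
main pole,antiaris toxicaria,100.00
main pole,anogeissus leiocarpa,100.00
main pole,avicennia germinans,100.00
main pole,azadirachta indica,100.00
main pole,baphia nitida,100.00
main pole,bridelia ferruginea,100.00
main pole,diospyros mespiliformis,100.00
main pole,gardenia ternifolia,100.00
main pole,tamarindus indica,100.00
main pole,tectona grandis,100.00
main pole,senna siamea,82.24
main pole,funtumia africana,44.20
main beam,borassus aethiopum,100.00
main beam,funtumia africana,100.00
main beam,leucaena leucocephala,100.00
main beam,senna siamea,100.00
main beam,azadirachta indica,70.87
main beam,bambusa vulgaris,67.90
wall lath,elaeis guineensis,100.00
wall lath,bambusa vulgaris,54.32
roof lath,bambusa vulgaris,100.00
roof lath,borassus aethiopum,92.42
roof lath,senna siamea,86.92
roof lath,azadirachta indica,86.41
binding material,cryptolepis nigrescens,100.00
binding material,eremospatha macrocarpa,100.00
binding material,musa sapientum,100.00
binding material,rhipsalis baccifera,100.00
thatch material,andropogon gayanus,100.00
thatch material,cocos nucifera,100.00
thatch material,cyperus papyrus,100.00
thatch material,raphia hookeri,100.00
thatch material,raphia palma-pinus,100.00
thatch material,typha domingensis,100.00
thatch material,elaeis guineensis,58.17
thatch material,bambusa vulgaris,49.38
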