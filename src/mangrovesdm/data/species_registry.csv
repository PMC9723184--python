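code,scientific_name,family,iucn_status,occ_archive,occ_field,intertidal_position
AR,Aegialitis rotundifolia,Plumbaginaceae,NT,35,60,low
AC,Aegiceras corniculatum,Myrsinaceae,LC,34,55,middle
AA,Avicennia alba,Acanthaceae,LC,45,60,low
AM,Avicennia marina,Acanthaceae,LC,56,60,middle
AO,Avicennia officinalis,Acanthaceae,LC,65,40,middle
BG,Bruguiera gymnorrhiza,Rhizophoraceae,LC,64,80,low
CD,Ceriops decandra,Rhizophoraceae,NT,50,30,low
CT,Ceriops tagal,Rhizophoraceae,LC,38,65,low
EA,Excoecaria agallocha,Euphorbiaceae,LC,25,25,mixed
HF,Heritiera fomes,Malvaceae,EN,10,15,mixed
KC,Kandelia candel,Rhizophoraceae,LC,23,35,mixed
LR,Lumnitzera racemosa,Combretaceae,LC,40,45,middle
NF,Nypa fruticans,Arecaceae,LC,25,25,high
PP,Phoenix paludosa,Arecaceae,NT,36,60,mixed
RM,Rhizophora mucronata,Rhizophoraceae,LC,45,47,middle
SA,Sonneratia apetala,Lythraceae,LC,60,66,middle
XG,Xylocarpus granatum,Meliaceae,LC,36,55,mixed
XM,Xylocarpus mekongensis,Meliaceae,NT,20,30,mixed
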