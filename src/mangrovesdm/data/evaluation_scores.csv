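species,roc,tss,kappa,boyce
Aegialitis rotundifolia,0.923,0.914,0.936,0.874
Aegiceras corniculatum,0.895,0.901,0.914,0.841
Avicennia alba,0.856,0.914,0.987,0.879
Avicennia marina,0.954,0.939,0.964,0.903
Avicennia officinalis,0.865,0.996,0.967,0.988
Bruguiera gymnorrhiza,0.821,0.761,0.988,0.859
Ceriops decandra,0.854,0.981,0.787,0.852
Ceriops tagal,0.882,0.978,0.932,0.847
Excoecaria agallocha,0.987,0.987,0.852,0.895
Heritiera fomes,0.862,0.869,0.847,0.866
Kandelia candel,0.889,0.941,0.873,0.888
Lumnitzera racemosa,0.841,0.789,0.896,0.989
Nypa fruticans,0.832,0.919,0.853,0.788
Phoenix paludosa,0.943,0.928,0.908,0.987
Rhizophora mucronata,0.938,0.976,0.909,0.967
Sonneratia apetala,0.994,0.806,0.994,0.969
Xylocarpus granatum,0.955,0.821,0.828,0.998
Xylocarpus mekongensis,0.951,0.842,0.847,0.906
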