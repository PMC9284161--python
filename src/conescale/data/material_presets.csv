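tissue,rh_percent,E_MPa
sclerenchyma_sim,30,800
sclerenchyma_sim,80,180
sclerenchyma_afm,30,800
sclerenchyma_afm,75,200
sclereid_regression,30,37
sclereid_regression,80,21
sclereid_afm,40,35
sclereid_afm,50,35
sclereid_afm,60,25
sclereid_afm,80,25
brown_tissue,30,52
brown_tissue,70,52
brown_tissue,80,43
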