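complex_id,dE_ele,dE_vdw,dG_gb,dG_sa,dG_sol_printed,dG_bind_printed,pic50
LSD1-04,-28.5803,-51.8392,45.2379,-6.0145,39.2235,-41.1960,6.917
LSD1-17,-14.5346,-45.4670,34.5108,-5.5613,28.9496,-31.0520,5.447
LSD1-21,-16.5911,-50.1944,37.4930,-6.2235,31.2696,-35.5160,6.117
LSD1-35,-15.5150,-38.2128,30.7264,-5.0611,25.6653,-28.0625,4.790
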