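species,area_current_lcc_nat_km2,reduced_pct_nat,area_current_lcc_pa_km2,reduced_pct_pa,loss_nat_rcp45,gain_nat_rcp45,loss_pa_rcp45,gain_pa_rcp45,loss_nat_rcp85,gain_nat_rcp85,loss_pa_rcp85,gain_pa_rcp85
D. gracilis,65048,67,21452,40,16.3,6.4,6.6,5.8,31.3,10.3,20.0,9.4
D. grandiflorus,62852,71,20137,41,6.5,8.1,1.1,9.1,8.5,12.7,1.6,13.8
D. hasseltii,56088,71,19633,40,3.3,0.0,2.4,0.0,1.8,0.4,1.0,0.3
D. kunstleri,8097,74,559,68,10.0,13.2,4.4,62.9,13.2,30.6,9.4,157.3
D. validus,10599,81,2424,48,0.0,110.1,0.0,116.3,0.0,193.9,0.0,212.4
H. acuminata,22475,63,7904,34,35.2,43.9,36.2,43.6,56.0,62.7,58.0,64.1
H. malibato,28181,63,10459,32,14.1,33.0,11.2,27.5,19.2,47.5,11.7,43.1
H. plagata,63728,63,21216,37,2.0,1.0,1.2,0.6,3.0,1.5,2.1,0.8
S. almon,58762,70,17747,37,6.7,2.7,3.8,4.4,7.9,5.2,2.3,8.6
S. assamica,33378,63,12428,36,34.6,8.6,39.2,6.0,50.2,10.1,54.4,7.2
S. astylosa,3921,61,1018,28,68.1,32.8,63.2,32.9,87.5,35.5,86.3,46.6
S. contorta,42472,67,17674,36,5.2,9.2,2.4,9.0,8.3,14.5,5.3,13.0
S. guiso,56517,67,18130,37,19.1,14.8,13.3,20.3,24.9,17.5,19.8,23.5
S. hopeifolia,19950,62,4734,31,55.9,17.7,50.8,30.0,71.8,19.2,69.4,30.8
S. ovata,8322,59,1954,26,39.9,50.7,19.8,92.5,56.9,53.0,37.3,90.5
S. palosapis,19441,54,7802,25,38.3,22.7,39.8,22.8,57.1,37.5,59.1,39.2
S. polysperma,44275,60,16496,30,15.1,15.5,15.7,11.2,27.0,20.8,27.6,15.2
S. virescens,5185,56,244,54,45.4,42.7,88.6,78.0,69.9,64.4,86.2,128.7
V. pachyphylla,5663,68,949,36,50.8,36.7,49.5,88.8,63.2,30.8,61.6,89.1
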