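species,body_mass_kg,standard_length_mm,anterior_force_N,posterior_force_N,mean_force_N,ant_ms_force_printed_N_per_kg,post_ms_force_printed_N_per_kg,anterior_stress_kPa,posterior_stress_kPa,mean_stress_kPa,total_dental_area_mm2,ant_ms_consistent,post_ms_consistent
Catoprion mento,0.033,105.0,0.6,2.0,1.1,17.5,61.2,243.1,862.3,551.5,13.5,False,False
Pygocentrus nattereri,0.728,167.0,18.8,42.0,31.7,25.8,57.7,649.6,3308.9,2448.6,56.5,True,True
Pygocentrus piraya,0.056,223.0,16.9,38.8,29.6,300.0,687.3,1397.4,4881.8,4678.9,154.5,False,False
Pygopristis denticulata,0.198,107.0,23.1,45.5,36.8,116.4,229.6,1330.2,14667.3,10096.2,61.4,False,False
Serrasalmus altispinis,0.051,129.0,21.3,63.5,43.8,421.8,1257.4,1486.2,11486.1,10360.5,63.4,False,False
Serrasalmus brandtii,0.233,190.0,32.7,100.9,69.0,140.5,433.4,1093.2,10139.5,6870.1,109.2,False,False
Serrasalmus eigenmanni,0.102,140.0,19.7,50.8,36.6,193.3,498.5,2039.4,10985.1,8075.9,43.4,False,False
Serrasalmus elongatus,0.042,134.0,11.1,50.4,25.4,266.2,1208.6,943.4,16801.9,5119.0,47.7,False,False
Serrasalmus geryi,0.04,115.0,12.0,29.1,21.2,299.3,725.7,1074.3,7266.0,5422.8,41.9,False,False
Serrasalmus manueli,0.064,127.0,10.8,29.1,18.0,168.2,453.3,790.0,4165.2,2188.9,57.1,False,False
Serrasalmus rhombeus,1.222,298.0,53.5,117.7,89.7,43.8,96.3,744.2,3384.0,2435.6,325.8,True,True
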