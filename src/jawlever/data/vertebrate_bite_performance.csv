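common_name,species,body_mass_kg,bite_force_N,force_per_mass_printed_N_per_kg,bite_stress_kPa,stress_per_mass_printed_kPa_per_kg,source,force_ratio_consistent,stress_ratio_consistent
Pike piranha,Serrasalmus elongatus,0.042,50.41,1208.77,167963,4027890,piranha_dataset,False,False
Red-spotted piranha,Serrasalmus altispinis,0.051,63.52,1257.79,114861,2274485,piranha_dataset,False,False
Gery's piranha,Serrasalmus geryi,0.04,29.06,724.69,72660,1811964,piranha_dataset,False,False
Darwin's finch,Geospiza magnirostris,0.033,44.0,1333.33,40000,1212121,Soons2015,True,True
Eigenmann's piranha,Serrasalmus eigenmanni,0.102,50.75,498.04,109804,1077564,piranha_dataset,False,False
Lobetoothed piranha,Pygopristis denticulata,0.198,45.47,229.64,146673,741148,piranha_dataset,False,False
Manuel's piranha,Serrasalmus manueli,0.064,29.07,452.85,41652,648781,piranha_dataset,False,False
San Francisco piranha,Pygocentrus piraya,0.056,38.76,692.18,30545,545449,piranha_dataset,False,False
Brandt's piranha,Serrasalmus brandtii,0.233,100.89,433.37,101395,435545,piranha_dataset,False,False
Wimple piranha,Catoprion mento,0.033,2.04,61.19,8623,258167,piranha_dataset,False,False
Redbelly piranha,Pygocentrus nattereri,0.728,41.99,57.68,135451,186059,piranha_dataset,True,True
Clevosaurus,Clevosaurus cambrica,1.5,10.3,6.87,171230,114153,ChambiTrowell2019,True,True
Jamaican fruit-eating bat,Artibeus jamaicensis,0.062,22.5,375.0,6450,107500,Dumont2009,False,False
Lesser short-nosed fruit bat,Cynopterus brachyotis,0.1,14.0,140.0,8710,87100,Dumont2009,True,True
Clevosaurus,Clevosaurus hudsoni,1.5,14.9,9.93,106090,70727,ChambiTrowell2019,True,True
Brown rat,Rattus norvegicus,0.5,,,25000,50000,Morris2022,False,True
Freshwater crocodile,Crocodylus johnsoni,43.0,1292.0,30.05,1871000,43512,Erickson2012,True,True
Grey squirrel,Sciurus carolinensis,0.75,,,25000,33333,Morris2022,False,True
Black piranha,Serrasalmus rhombeus,1.222,117.73,96.34,33840,27692,piranha_dataset,True,True
Long-fingered lemur,Daubentonia madagascariensis,2.62,,,35000,13384,Morris2022,False,False
American alligator,Alligator mississippiensis,142.0,9452.0,66.56,1568000,11042,Erickson2012,True,True
Saltwater crocodile,Crocodylus porosus,272.0,16414.0,60.35,2473000,9092,Erickson2012,True,True
Black caiman,Melanosuchus niger,59.0,2696.0,45.69,509000,8627,Erickson2012,True,True
Orinoco crocodile,Crocodylus intermedius,182.0,6276.0,34.48,1388000,7626,Erickson2012,True,True
Beaver,Castor canadensis,50.0,,,40000,800,Morris2022,False,True
Spotted hyena,Crocuta crocuta,80.0,2014.0,25.18,46000,575,Tanner2008,True,True
Crested porcupine,Hystrix cristata,27.0,,,15000,556,Morris2022,False,True
T. rex,Tyrannosaurus rex,5654.0,34522.0,6.11,2974000,526,Gignac2017,True,True
Placoderm,Dunkleosteus terrelli,1000.0,5363.0,5.36,147000,147,Anderson2007,True,True
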