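species,genus,test_type,endpoint,value,unit,source_id,exclude,notes
Asellus aquaticus,Asellus,acute,EC50,124000,ug/L,B42,,
Ceriodaphnia dubia,Ceriodaphnia,acute,LC50,36700,ug/L,B43,,
Ceriodaphnia dubia,Ceriodaphnia,acute,LC50,30100,ug/L,B43,,
Chironomus javanus,Chironomus,acute,LC50,1650,ug/L,B44,,
Daphnia magna,Daphnia,acute,LC50,76000,ug/L,B45,,
Daphnia magna,Daphnia,acute,EC50,9600,ug/L,B46,,
Daphnia magna,Daphnia,acute,LC50,21000,ug/L,B47,,
Daphnia pulex,Daphnia,acute,LC50,12900,ug/L,B48,,
Daphnia pulex,Daphnia,acute,LC50,15800,ug/L,B48,,
Daphnia pulex,Daphnia,acute,LC50,17400,ug/L,B48,,
Daphnia pulex,Daphnia,acute,LC50,9000,ug/L,B49,,
Daphnia pulex,Daphnia,acute,LC50,2800,ug/L,B49,,
Duttaphrynus melanostictus,Duttaphrynus,acute,LC50,400,ug/L,B50,,
Gambusia affinis,Gambusia,acute,LC50,133000,ug/L,B51,,
Gambusia affinis,Gambusia,acute,LC50,74000,ug/L,B51,,
Lepomis macrochirus,Lepomis,acute,LC50,20300,ug/L,B48,,
Melanoides tuberculata,Melanoides,acute,LC50,8490,ug/L,B50,,
Nais elinguis,Nais,acute,LC50,123,ug/L,B50,,
Orconectes limosus,Orconectes,acute,LC50,32000,ug/L,B52,,
Physa gyrina,Physa,acute,LC50,12100,ug/L,B48,,
Pimephales promelas,Pimephales,acute,LC50,21800,ug/L,B48,,
Ptychocheilus oregonensis,Ptychocheilus,acute,LC50,54800,ug/L,B48,,
Salmo trutta,Salmo,acute,LC50,28000,ug/L,B53,,
Salmo trutta,Salmo,acute,LC50,47000,ug/L,B53,,
Stenocypris major,Stenocypris,acute,LC50,279,ug/L,B50,,
Tubifex tubifex,Tubifex,acute,EC50,102000,ug/L,B54,,
Tubifex tubifex,Tubifex,acute,EC50,86100,ug/L,B55,,
Tubifex tubifex,Tubifex,acute,EC50,95400,ug/L,B55,,
Tubifex tubifex,Tubifex,acute,EC50,71300,ug/L,B55,,
Tubifex tubifex,Tubifex,acute,EC50,125000,ug/L,B55,,
Xenopus laevis,Xenopus,acute,EC50,1000000,ug/L,B56,,
Chlorella vulgaris,Chlorella,chronic,LOEC,6000,ug/L,B57,,
Chlorella vulgaris,Chlorella,chronic,NOEC,3000,ug/L,B57,,
Daphnia pulex,Daphnia,chronic,LOEC,1310,ug/L,B48,,
Daphnia pulex,Daphnia,chronic,LOEC,1310,ug/L,B48,,
Daphnia pulex,Daphnia,chronic,LOEC,1310,ug/L,B48,,
Daphnia pulex,Daphnia,chronic,MATC,960,ug/L,B48,,
Daphnia pulex,Daphnia,chronic,MATC,960,ug/L,B48,,
Daphnia pulex,Daphnia,chronic,MATC,960,ug/L,B48,,
Daphnia pulex,Daphnia,chronic,NOEC,700,ug/L,B48,,
Daphnia pulex,Daphnia,chronic,NOEC,700,ug/L,B48,,
Daphnia pulex,Daphnia,chronic,NOEC,700,ug/L,B48,,
Lecane quadridentata,Lecane,chronic,LOEC,100,ug/L,B58,,
Lecane quadridentata,Lecane,chronic,NOEC,10,ug/L,B58,,
Pimephales promelas,Pimephales,chronic,LOEC,1010,ug/L,B48,,
Pimephales promelas,Pimephales,chronic,MATC,570,ug/L,B48,,
Pimephales promelas,Pimephales,chronic,NOEC,320,ug/L,B48,,
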