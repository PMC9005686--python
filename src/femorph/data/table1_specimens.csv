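higher_order,species,abbreviation,institution,number,locomotor_mode,sides,femoral_length_mm,digitization,juvenile
Non-archosaurian Archosauriformes,Euparkeria capensis,Eup,SAM PK,5867,Q,R,52.2,uCT,0
Non-archosaurian Archosauriformes,Phytosauridae,Phy,PEFO,23347,Q,L,375.4,Ph,0
Non-archosaurian Archosauriformes,Phytosauridae,Phy,PEFO,31219,Q,L,413.3,Ph,0
"Pseudosuchia, Erpetosuchidae",Parringtonia gracilis,Par,NMT,RB188,Q,R,71.9,SS,0
"Pseudosuchia, Erpetosuchidae",Parringtonia gracilis,Par,NMT,RB246,Q,"L, R","70.6, 70.2",SS,0
"Pseudosuchia, Ornithosuchidae",Riojasuchus tenuisceps,Rio,PVL,3827,C,L,154.4,CT,0
"Pseudosuchia, Ornithosuchidae",Riojasuchus tenuisceps,Rio,PVL,3828,C,L,170.7,CT,0
"Pseudosuchia, Suchia",Suchia indet.,Suc,NMT,RB187,Q,R,138.7,SS,0
"Pseudosuchia, Suchia",Revueltosaurus callenderi,Rev,PEFO,34269,Q,L,81.5,Ph,0
"Pseudosuchia, Suchia",Revueltosaurus callenderi,Rev,PEFO,34561,Q,L,92.1,Ph,0
"Pseudosuchia, Aetosauridae",Paratypothorax sp.,Par,TTUP,12547,Q,R,480.5,Ph,0
"Pseudosuchia, Aetosauria",Typothorax coccinarum,Typ,NMMNH,P-11775,Q,L,198,Ph,0
"Pseudosuchia, Aetosauria",Typothorax coccinarum,Typ,NMMNH,P-11778,Q,L,254.9,Ph,0
"Pseudosuchia, Paracrocodylomorpha",Nundasuchus songeaensis,Nun,NMT,RB48,Q,R,230.9,SS,0
"Pseudosuchia, Poposauridea",Poposaurus gracilis,Pop,YPM,57100,B,"L, R","333.8, 339.9",CT,0
"Pseudosuchia, Poposauridea",Shuvosaurus inexpectatus,Shu,NMMNH,P-4695,B,R,128.7,Ph,0
"Pseudosuchia, Poposauridea",Shuvosaurus inexpectatus,Shu,TTUP,18307,B,L,202.7,Ph,0
"Pseudosuchia, Poposauridea",Shuvosaurus inexpectatus,Shu,TTUP,18321,B,L,197.6,Ph,0
"Pseudosuchia, Poposauridea",Shuvosaurus inexpectatus,Shu,TTUP,18336,B,L,241.1,Ph,0
"Pseudosuchia, Poposauridea",Shuvosaurus inexpectatus,Shu,TTUP,9001,B,L,230.9,SS,0
"Pseudosuchia, Loricata",Loricata indet.,Lor,NMMNH,P-36144,C,R,374.8,Ph,0
"Pseudosuchia, Rauisuchidae",Postosuchus kirkpatricki,Pos,TTUP,9000,C,L,504.5,Ph,0
"Pseudosuchia, Rauisuchidae",Postosuchus kirkpatricki,Pos,TTUP,9002,C,"L, R","373.7, 388.3",Ph,0
"Pseudosuchia, Crocodylomorpha",Hesperosuchus agilis,Hes,AMNH,FR6758,Q,L,136.5,SS,0
"Pseudosuchia, Crocodylomorpha",Crocodylomorpha indet.,Crm,TTUP,11443,Q,R,109.8,Ph,0
"Pseudosuchia, Crocodylomorpha",Terrestrisuchus gracilis,Ter,NHMUK PV,R7562,Q,R,82.1,uCT,0
"Pseudosuchia, Crocodylomorpha",Terrestrisuchus gracilis,Ter,NHMUK PV,R10002,Q,R,63.7,uCT,0
"Pseudosuchia, Crocodylomorpha",Terrestrisuchus gracilis,Ter,Composite of proximal R7562 and distal R10002,NA,Q,R,54.4,uCT,0
"Pseudosuchia, Crocodylomorpha",Protosuchus richardsoni,Pro,AMNH,3024,Q,R,110.2,CT,0
"Pseudosuchia, Crocodylomorpha",Crocodylus niloticus,Cro,RVC,DDNC01,Q,R,66.8,CT,1
"Pseudosuchia, Crocodylomorpha",Crocodylus niloticus,Cro,RVC,DDNC02,Q,R,49.2,CT,1
"Pseudosuchia, Crocodylomorpha",Crocodylus niloticus,Cro,RVC,DDNC03,Q,R,58.9,CT,1
"Pseudosuchia, Crocodylomorpha",Crocodylus niloticus,Cro,RVC,DDNC04,Q,R,70.5,CT,1
"Pseudosuchia, Crocodylomorpha",Crocodylus niloticus,Cro,RVC,FNC5,Q,L,271.9,CT,0
"Avemetatarsalia, Aphanosauria",Teleocrater rhadinus,Tel,NHMUK PV,R 6795,Q,R,168.5,Ph,0
"Avemetatarsalia, Aphanosauria",Teleocrater rhadinus,Tel,NMT,RB 843,Q,R,147.4,SS,0
"Avemetatarsalia, Aphanosauria",Teleocrater rhadinus,Tel,NMT,RB 844,Q,R,143.1,SS,0
"Avemetatarsalia, Aphanosauria",Teleocrater rhadinus,Tel,NMT,RB 845,Q,R,127.1,SS,0
"Avemetatarsalia, Lagerpetidae",Kongonaphon kely,Kon,UA,10618,C,R,38.6,uCT,0
"Avemetatarsalia, Lagerpetidae",Dromomeron gregorii,Dro,TMM,31100 464,C,R,91.9,SS,0
"Avemetatarsalia, Lagerpetidae",Dromomeron gregorii,Dro,TMM,31100 764,C,R,57.3,SS,1
"Avemetatarsalia, Lagerpetidae",Dromomeron gregorii,Dro,TMM,31100 1308,C,R,81.5,SS,1
"Avemetatarsalia, Dinosauriformes",Lagosuchus lilloensis,Lag,PVL,4670,B,R,46.7,CT,0
"Avemetatarsalia, Silesauridae",Asilisaurus kongwe,Asi,NMT,RB 159,C,L,140.6,Ph,0
"Avemetatarsalia, Silesauridae",Asilisaurus kongwe,Asi,NMT,RB 169,C,L,71.4,SS,1
"Avemetatarsalia, Silesauridae",Silesauridae indet.,Sid,TMM,31100 185,C,L,139.8,SS,0
"Avemetatarsalia, Silesauridae",Silesauridae indet.,Sid,TMM,31100 1303,C,L,145.9,SS,0
"Avemetatarsalia, Silesauridae",Silesaurus opolensis,Sil,ZPAL,361.23,C,L,192.8,SS,0
"Avemetatarsalia, Ornithischia",Lesothosaurus diagnosticus,Les,NHMUK PV,RUB 17,B,R,99.1,SS,0
"Avemetatarsalia, Sauropodomorpha",Mussaurus patagonicus,Mus,MPM,1813,C,R,114.3,uCT,1
"Avemetatarsalia, Sauropodomorpha",Mussaurus patagonicus,Mus,MLP,60 III 20-22,B,R,814.7,Ph,0
"Avemetatarsalia, Sauropodomorpha",Plateosaurus sp.,Pla,GPIT,RE7288,B,R,559.7,CT,0
"Avemetatarsalia, Sauropodomorpha",Plateosaurus sp.,Pla,SMNS,13200a+e,B,L,677.9,SS,0
"Avemetatarsalia, Sauropodomorpha",Plateosaurus sp.,Pla,SMNS,91300,B,R,614.2,SS,0
"Avemetatarsalia, Sauropodomorpha",Plateosaurus sp.,Pla,SMNS,91310,B,L,607.5,SS,0
"Avemetatarsalia, Sauropodomorpha",Plateosaurus sp.,Pla,SMNS,91297,B,L,604.8,SS,0
"Avemetatarsalia, Theropoda",Staurikosaurus pricei,Sta,MCZ,1699,B,R,220.3,Ph,0
"Avemetatarsalia, Theropoda",Herrerasaurus ischigualastensis,Her,MACN,18060,B,L,278.6,SS,0
"Avemetatarsalia, Theropoda",Herrerasaurus ischigualastensis,Her,PVL,2566,B,R,435.1,SS,0
"Avemetatarsalia, Theropoda",Herrerasaurus ischigualastensis,Her,PVSJ,373,B,L,335.5,SS,0
"Avemetatarsalia, Theropoda",Tawa hallae,Taw,GR,244,B,R,110.2,SS,1
"Avemetatarsalia, Theropoda",Tawa hallae,Taw,GR,1033,B,R,168.5,SS,0
"Avemetatarsalia, Theropoda",Tawa hallae,Taw,GR,1054,B,R,202.9,SS,0
"Avemetatarsalia, Neotheropoda",Neotheropoda indet.,Neo,GR,1046,B,R,207.7,SS,0
"Avemetatarsalia, Neotheropoda",Coelophysis bauri,Coe,UCMP,129618,B,R,252.7,SS,0
"Avemetatarsalia, Neotheropoda",Coelophysis bauri,Coe,AMNH,FARB 32843,B,R,124.8,SS,1
"Avemetatarsalia, Neotheropoda",Dilophosaurus wetherilli,Dil,UCMP,37302,B,L,586.3,CT,0
"Avemetatarsalia, Avialae",Archaeopteryx lithographica,Arc,HMN,1880,B,R,56.9,SS,0
"Avemetatarsalia, Avialae",Rahonavis ostromi,Rah,UA,8656,B,L,85.3,uCT,0
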