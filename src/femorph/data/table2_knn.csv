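name,input_mode,predicted_mode
Archaeopteryx HMN 1880,B,B
Asilisaurus NMT RB159,I,Q
Asilisaurus NMT RB169,I,Q
Coelophysis AMNH FARB 32843,B,B
Coelophysis UCMP 129618,B,B
Crocodylus DDNC01,Q,Q
Crocodylus DDNC02,Q,Q
Crocodylus DDNC03,Q,Q
Crocodylus DDNC04,Q,Q
Crocodylus FNC5,Q,Q
Dilophosaurus UCMP 37302,B,B
Dromomeron TMM 31100-464,I,B
Dromomeron TMM 31100-764,I,Q
Dromomeron TMM 31100-1308,I,Q
Euparkeria SAM-PK-5867,Q,Q
Herrerasaurus MACN 18060,B,B
Herrerasaurus PVL 2566,B,B
Herrerasaurus PVSJ 373,B,B
Hesperosuchus AMNH FR 6758,Q,Q
Kongonaphon UA 10618,I,B
Lesothosaurus NHMUK RUB17,B,B
Lagosuchus PVL 4670,B,B
Mussaurus MLP60-III-20-22,B,B
Mussaurus MPM 1813,I,B
Neotheropoda GR1046,B,B
Nundasuchus NMT RB48,Q,Q
Paratypothorax TTU-P12547,Q,B
Parringtonia NMT RB188,Q,Q
Parringtonia NMT RB426 (L),Q,Q
Parringtonia NMT RB426 (R),Q,Q
Phytosauridae PEFO 23347,Q,Q
Phytosauridae PEFO 31219,Q,Q
Plateosaurus GPIT RE7288,B,B
Plateosaurus SMNS 13200a+e,B,B
Plateosaurus SMNS 91297,B,B
Plateosaurus SMNS 91300,B,B
Plateosaurus SMNS 91310,B,B
Poposaurus YPM 57100 (L),B,Q
Poposaurus YPM 57100 (R),B,Q
Postosuchus TTU-P9000,I,B
Postosuchus TTU-P9002 (L),I,Q
Postosuchus TTU-P9002 (R),I,Q
Protosuchus AMNH FR 3024,Q,Q
Rahonavis UA8656,B,B
Loricata NMMNH P-36144,I,Q
Revueltosaurus PEFO 34269,Q,Q
Revueltosaurus PEFO 34561,Q,Q
Riojasuchus PVL 3827,I,B
Riojasuchus PVL 3828,I,Q
Shuvosaurus NMMNHP-4695,B,B
Shuvosaurus TTU-P18307,B,Q
Shuvosaurus TTU-P18321,B,B
Shuvosaurus TTU-P18336,B,B
Shuvosaurus TTU-P9001,B,Q
Silesaurid TMM 31100-1303,I,B
Silesaurid TMM31100-185,I,B
Silesaurus ZPAL361.23,I,B
Sphenosuchian TTU-P11443,Q,Q
Staurikosaurus MCZ 1699,B,B
Suchian NMT RB187,Q,Q
Tawa GR 1033,B,B
Tawa GR 1054,B,B
Tawa GR 244,B,B
Teleocrater NHMUK PV R6795,Q,Q
Teleocrater NMT RB843,Q,Q
Teleocrater NMT RB844,Q,Q
Teleocrater NMT RB845,Q,Q
Terrestrisuchus 721.3,Q,Q
Terrestrisuchus R10002,Q,Q
Terrestrisuchus Composite,Q,Q
Typothorax NMMNH-P11775,Q,Q
Typothorax NMMNH-P11778,Q,Q
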