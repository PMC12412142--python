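name,formula,adduct,polarity,expected_mz,nominal_label,log_kow,cid,cas,erratum_note
Acetaminophen,C8H9NO2,+H,POS,152.0706,152,0.46,1983,103-90-2,
Anhydro erythromycin,C37H65NO12,+H,POS,716.4580,716,3.2,83949,23893-13-2,
Caffeine,C8H10N4O2,+H,POS,195.0877,195,-0.07,2519,58-08-2,
Carbamazepine,C15H12N2O,+H,POS,237.1022,237,2.45,2554,294-46-4,
Clindamycin sulfoxide,C18H33ClN2O6S,+H,POS,441.1821,441,1.1,73046007,22341-46-5,
Fexofenadine,C32H39NO4,+H,POS,502.2952,502,3,3348,83799-24-0,
6:2 Fluorotelomer sulfonic acid,C8H5F13O3S,-H,NEG,426.9679,426,3.9,119688,27619-97-2,
Oxazepam,C15H11ClN2O2,+H,POS,287.0582,287,2.24,4616,604-75-1,
Perfluorohexanoic acid,C6HF11O2,-H,NEG,312.9728,312,3.6,67542,307-24-4,
Perfluorooctane sulfonamide,C8H2F17NO2S,-H,NEG,497.9462,497,5.8,69785,754-91-6,
Perfluorooctanoic acid,C8HF15O2,-H,NEG,412.9664,412,6.3,9554,335-67-1,
Perfluoropentanoic acid,C6HF9O2,-H,NEG,262.9760,262,2.9,75921,2706-90-3,published expected m/z matches C5HF9O2; formula/mass inconsistent in the source panel
Verapamil,C27H38N2O4,+H,POS,455.2904,455,2.15,2520,52-53-9,
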