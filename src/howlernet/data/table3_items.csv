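species,items_continuous,pct_core_continuous,pct_periphery_continuous,items_fragments,pct_core_fragments,pct_periphery_fragments
Brosimum alicastrum,IL|MF|IF,100,0,IL|MF|IF,100,0
Ficus sp.,-,0,0,IL|MF|IF,100,0
Abuta panamensis,MF,0,45,MF|IL,100,0
Acacia usumacintensis,IL,0,45,IL,95,5
Ampelocera hottlei,MF|ML,100,0,MF,100,0
Araceae sp.,-,0,0,IL,95,5
Bignoneaceae sp.,IL,0,100,IL|MF,100,0
Cecropia obtusifolia,MF|IL,85,15,IL|MF,95,0
Cojoba arborea,IL,0,100,IL,100,0
Dialium guianense,MF,100,0,MF,100,0
Licania platypus,B|IL,45,55,IL,100,0
Machaerium sp.,IL|FL|MF,0,100,IL,100,0
Pourouma bicolor,MF,100,0,MF|IL,90,10
Trophis racemosa,-,0,0,IL,100,0
Brosimum lactescens,MF,100,0,MF,25,75
Castilla elastic,MF,0,100,IL,40,60
Combretum sp.,-,0,0,IL,0,80
Hirtella Americana,-,0,0,MF,30,0
Liana sp.,-,0,0,IL,20,80
Paulinia fibrigera,IL,50,50,IL,20,80
Pseudolmedia oxyphillaria,-,0,0,IL,30,70
Talauma Mexicana,P,0,100,P,0,90
Albizia leucocalyx,ML|IF,100,0,IL,0,100
Garcinia intermedia,MF,95,5,MF,0,100
Inga sp.,IL,60,0,IL,0,100
Platimiscium yucatanum,IL,0,45,IL,0,100
Sapindaceae sp.,-,0,0,MF,0,100
Schizolobium arboreum,P,0,100,P,0,100
Spondia mombin,-,0,0,MF,0,100
Bursera simaruba,-,0,0,IL,0,100
Ficus tecolotensis,MF|IL,100,0,-,0,0
Bravaisia sp.,IL|P,55,45,-,0,0
Maclura tinctoria,IL,100,0,-,0,0
Ficus yoponensis,IL,0,100,-,0,0
Lonchocarpus sp.,ML,0,100,-,0,0
Malpigiaceae sp.,FL,30,70,-,0,0
Zanthoxylum riedelianum,IL,0,100,-,0,0
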