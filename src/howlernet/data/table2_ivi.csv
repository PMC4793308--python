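habitat,family,species,ivi
continuous,Moraceae,Brosimum alicastrum,0.52
continuous,Meliaceae,Guarea excelsia,0.40
continuous,Moraceae,Ficus sp.,0.36
continuous,Ulmaceae,Ampelocera hottlei,0.22
continuous,Burseraceae,Bursera simaruba,0.19
continuous,Anacardiaceae,Spondias mombin,0.15
continuous,Moraceae,Trophis racemosa,0.15
continuous,Fabaceae,Acacia usumacintensis,0.13
continuous,Moraceae,Castilla elastica,0.12
continuous,Fabaceae,Albizia leucocalyx,0.11
fragment,Fabaceae,Dialium guianense,0.53
fragment,Moraceae,Brosimum alicastrum,0.46
fragment,Fabaceae,Pterocarpus bayesii,0.28
fragment,Ulmaceae,Ampelocera hottlei,0.26
fragment,Moraceae,Ficus sp.,0.21
fragment,Moraceae,Castilla elastica,0.19
fragment,Chrysobalanaceae,Licania platypus,0.18
fragment,Sapotaceae,Pouteria campechiana,0.16
fragment,Moraceae,Trophis racemosa,0.15
fragment,Meliaceae,Guarea excelsia,0.11
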