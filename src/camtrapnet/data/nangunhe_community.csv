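class_name,order_name,family,species,n_photographs,rai_printed,occupancy,selected
Mammalia,Proboscidea,Elephantidae,Elephas maximus,307,74.6,50,True
Mammalia,Artiodactyla,Cervidae,Rusa unicolor,731,91.0,61,True
Mammalia,Artiodactyla,Cervidae,Muntiacus vaginalis,381,65.7,44,True
Mammalia,Artiodactyla,Suidae,Sus scrofa,32,17.9,12,True
Mammalia,Artiodactyla,Bovidae,Capricornis milneedwardsii,21,10.4,7,False
Mammalia,Primates,Cercopithecidae,Macaca mulatta,80,32.8,22,True
Mammalia,Primates,Cercopithecidae,Macaca leonina,21,13.4,9,True
Mammalia,Primates,Cercopithecidae,Trachypithecus crepusculus,1,1.5,1,False
Mammalia,Rodentia,Hystricidae,Atherurus macrourus,33,14.9,10,True
Mammalia,Rodentia,Hystricidae,Hystrix brachyura subcristata,58,23.9,16,True
Mammalia,Rodentia,Sciuridae,Callosciurus erythraeus,19,20.9,14,True
Mammalia,Carnivora,Felidae,Prionailurus bengalensis,12,14.9,10,True
Mammalia,Carnivora,Mustelidae,Melogale moschata,5,4.5,3,False
Mammalia,Carnivora,Mustelidae,Martes flavigula,3,4.5,1,False
Mammalia,Carnivora,Viverridae,Viverricula indica,5,3.0,2,False
Mammalia,Carnivora,Viverridae,Paradoxurus hermaphroditus,8,4.5,3,False
Mammalia,Carnivora,Viverridae,Paguma larvata,1,1.5,1,False
Mammalia,Carnivora,Ursidae,Ursus thibetanus,2,1.5,1,False
Aves,Galliformes,Phasianidae,Gallus gallus,101,18.0,12,True
Aves,Galliformes,Phasianidae,Lophura nycthemera,11,9.0,6,False
Aves,Galliformes,Phasianidae,Arborophila atrogularis,1,1.5,1,False
Aves,Accipitriformes,Accipitridae,Pernis ptilorhynchus,1,1.5,1,False
Aves,Accipitriformes,Accipitridae,Spilornis cheela,3,3.0,2,False
Aves,Passeriformes,Sittidae,Sitta nagaensis,1,1.5,1,False
Aves,Passeriformes,Sittidae,Sitta frontalis,1,1.5,1,False
Aves,Passeriformes,Turdidae,Turdus dissimilis,13,10.4,1,False
Aves,Passeriformes,Phylloscopidae,Phylloscopus tephrocephalus,1,1.5,1,False
Aves,Passeriformes,Pellorneidae,Pellorneum ruficeps,3,4.5,3,False
Aves,Passeriformes,Pellorneidae,Schoeniparus dubius,1,1.5,1,False
Aves,Passeriformes,Timaliidae,Pomatorhinus schisticeps,1,1.5,1,False
Aves,Passeriformes,Leiothrichidae,Leiothrix argentauris,1,1.5,1,False
Aves,Passeriformes,Muscicapidae,Copsychus malabaricus,1,1.5,1,False
Aves,Passeriformes,Muscicapidae,Copsychus saularis,2,1.5,1,False
Aves,Passeriformes,Muscicapidae,Myophonus caeruleus,3,3.0,2,False
Aves,Passeriformes,Pycnonotidae,Alophoixus flaveolus,1,1.5,1,False
Aves,Passeriformes,Alcippeidae,Alcippe fratercula,1,1.5,1,False
Aves,Columbiformes,Columbidae,Streptopelia decaocto,1,1.5,1,False
Aves,Columbiformes,Columbidae,Chalcophaps indica,4,6.0,4,False
Aves,Columbiformes,Columbidae,Macropygia unchall,2,1.5,1,False
Aves,Piciformes,Picidae,Chrysophlegma flavinucha,1,1.5,1,False
Aves,Coraciiformes,Meropidae,Nyctyornis athertoni,1,1.5,1,False
Aves,Bucerotiformes,Bucerotidae,Anthracoceros albirostris,1,1.5,1,False
Aves,Strigiformes,Strigidae,Glaucidium cuculoides,1,1.5,1,False
Reptilia,Squamata,Varanidae,Varanus salvator,1,1.5,1,False
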