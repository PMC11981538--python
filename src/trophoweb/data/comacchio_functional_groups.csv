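taxon,functional_group,pre,post
Alitta succinea,Surface Deposit Feeders,x,
Bivalvia larvae,Suspension Feeders,x,
Chironomus salinarius,Subsurface Deposit Feeders,x,
Dicentrarchus labrax,Dicentrarchus labrax,x,
Haminoea hydatis,Surface Deposit Feeders,x,
Hydrobia sp.,Surface Deposit Feeders,x,
Idotea balthica,Scrapers,x,
Lamprothamnium papulosum,Lamprothamnium papulosum,x,
Littorina sp.,Grazers,x,
Maja squinado,Maja squinado,x,
Palaemon elegans,Shrimp,x,
Platichthys flesus,Flatfish,x,
Polychaeta larvae,Surface Deposit Feeders,x,
Polychaeta mobile,Benthic Predators,x,
Ruppia cirrhosa,Ruppia cirrhosa,x,
Small invertebrate larvae,Filter Feeders,x,
Solea solea,Flatfish,x,
Tritia neritea,Grazers,x,
Upogebia pusilla,Upogebia pusilla,x,
Acartia,Surface Deposit Feeders,,x
Ardea alba,Birds,,x
Ardea cinerea,Birds,,x
Balanidae sp.,Suspension Feeders,,x
Chironomidae,Subsurface Deposit Feeders,,x
Ciliata,Surface Deposit Feeders,,x
Crangon crangon,Shrimp,,x
Cumacea sp.,Grazers,,x
Diatom,Diatom,,x
Dinoflagellata,Dinoflagellata,,x
Egretta garzetta,Birds,,x
Engraulis encrasicolus,Engraulis encrasicolus,,x
Hydrobiidae,Surface Deposit Feeders,,x
Malacostraca,Grazers,,x
Mysida,Grazers,,x
Nanocyanobacteria,Nanocyanobacteria,,x
Nemertea,Benthic Predators,,x
Nereididae sp.,Surface Deposit Feeders,,x
Palaemon sp.,Shrimp,,x
Phalacrocorax carbo,Birds,,x
Phalacrocorax pygmaeus,Birds,,x
Picocyanobacteria,Picocyanobacteria,,x
Podiceps cristatus,Birds,,x
Podiceps nigricollis,Birds,,x
Polychaeta,Surface Deposit Feeders,,x
Shrimp,Shrimp,,x
Spionidae,Benthic Predators,,x
Sterna hirundo,Birds,,x
Sterna sandvicensis,Birds,,x
Syllidae sp.,Surface Deposit Feeders,,x
Tanaidacea sp.,Grazers,,x
Turbellaria,Benthic Predators,,x
Zoea larvae,Grazers,,x
Actiniaria,Actiniaria,x,x
Amphipoda,Scrapers,x,x
Anguilla anguilla,Anguilla anguilla,x,x
Anguilla anguilla Juvenile,Anguilla anguilla,x,x
Aphanius fasciatus,Aphanius fasciatus,x,x
Atherina boyeri,Atherina boyeri,x,x
Bivalvia,Suspension Feeders,x,x
Carcinus aestuarii,Carcinus aestuarii,x,x
Chelon auratus,Mugil spp.,x,x
Chelon ramada,Mugil spp.,x,x
Chelon saliens,Mugil spp.,x,x
Copepoda,Copepoda,x,x
Crustacea,Scrapers,x,x
Detritus,Detritus,x,x
Gammarus sp.,Scrapers,x,x
Gastropoda,Grazers,x,x
Gobidae,Gobidae,x,x
Monocorophium insidiosum,Surface Deposit Feeders,x,x
Mugil cephalus,Mugil spp.,x,x
Oligochaeta,Subsurface Deposit Feeders,x,x
Polychaeta sedentary,Surface Deposit Feeders,x,x
Rotifera,Filter Feeders,x,x
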