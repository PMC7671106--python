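species,habitat,synthetic_category,coarse_category,Vermes,Stationary benthic items,Tentacles and appendages,Benthic arthropods,Pelagic arthropods,Squishy swimmers
Abyssocottus korotneffi,Freshwater,Benthic arthropods,Invertivore,0.00,0.00,0.00,0.96,0.00,0.00
Artedius fenestralis,Marine,Benthic arthropods,Omnivore,0.19,0.12,0.00,0.64,0.00,0.00
Blepsias cirrhosus,Marine,Benthic arthropods,Planktivore,0.00,0.00,0.00,0.59,0.39,0.00
Chitonotus pugetensis,Marine,Benthic arthropods,Invertivore,0.08,0.00,0.00,0.84,0.01,0.07
Clinocottus acuticeps,Marine,Benthic arthropods,Invertivore,0.00,0.00,0.00,0.95,0.06,0.00
Clinocottus analis,Marine,Benthic arthropods,Omnivore,0.24,0.17,0.01,0.49,0.02,0.01
Clinocottus embryum,Marine,Tentacles and appendages,Omnivore,0.09,0.09,0.39,0.39,0.05,0.00
Clinocottus globiceps,Marine,Stationary benthic items,Omnivore,0.02,0.74,0.02,0.01,0.13,0.00
Clinocottus recalvus,Marine,Stationary benthic items,Omnivore,0.00,0.43,0.07,0.14,0.36,0.00
Comephorus dybowskii,Freshwater,Pelagic arthropods,Planktivore,0.00,0.00,0.00,0.00,0.93,0.08
Cottocomephorus grewingki,Freshwater,Pelagic arthropods,Planktivore,0.00,0.00,0.00,0.00,0.80,0.20
Cottus aleuticus,Freshwater,Benthic arthropods,Insectivore,0.00,0.05,0.00,0.90,0.00,0.05
Cottus asper,Freshwater,Benthic arthropods,Insectivore,0.03,0.00,0.00,0.90,0.00,0.08
Cottus asperrimus,Freshwater,Benthic arthropods,Insectivore,0.02,0.19,0.00,0.71,0.06,0.00
Cottus baileyi,Freshwater,Benthic arthropods,Insectivore,0.00,0.00,0.00,1.00,0.00,0.00
Cottus bairdii,Freshwater,Benthic arthropods,Insectivore,0.03,0.05,0.00,0.90,0.00,0.03
Cottus beldingii,Freshwater,Stationary benthic items,Omnivore,0.20,0.67,0.00,0.13,0.01,0.05
Cottus carolinae,Freshwater,Benthic arthropods,Insectivore,0.00,0.00,0.00,0.87,0.00,0.12
Cottus cognatus,Freshwater,Benthic arthropods,Omnivore,0.00,0.00,0.00,0.97,0.00,0.02
Cottus confusus,Freshwater,Benthic arthropods,Insectivore,0.00,0.00,0.00,0.77,0.00,0.23
Cottus extensus,Freshwater,Pelagic arthropods,Invertivore,0.00,0.00,0.00,0.00,1.00,0.00
Cottus gobio,Freshwater,Benthic arthropods,Insectivore,0.08,0.00,0.00,0.62,0.00,0.00
Cottus gulosus,Freshwater,Benthic arthropods,Insectivore,0.10,0.00,0.00,0.85,0.00,0.05
Cottus hubbsi,Freshwater,Benthic arthropods,Insectivore,0.00,0.00,0.00,0.90,0.00,0.10
Cottus klamathensis,Freshwater,Benthic arthropods,Insectivore,0.00,0.00,0.00,1.00,0.00,0.00
Cottus leiopomus,Freshwater,Benthic arthropods,Insectivore,0.00,0.00,0.00,1.00,0.00,0.00
Cottus perplexus,Freshwater,Benthic arthropods,Piscivore,0.00,0.03,0.00,0.93,0.00,0.05
Cottus pitensis,Freshwater,Benthic arthropods,Insectivore,0.00,0.00,0.00,1.00,0.00,0.00
Cottus poecilopus,Freshwater,Benthic arthropods,Omnivore,0.05,0.00,0.00,0.90,0.00,0.05
Cottus pollux,Freshwater,Benthic arthropods,Insectivore,0.00,0.00,0.00,1.00,0.00,0.00
Cottus rhotheus,Freshwater,Squishy swimmers,Insectivore,0.00,0.00,0.00,0.50,0.00,0.50
Cottus ricei,Freshwater,Benthic arthropods,Insectivore,0.00,0.00,0.00,1.00,0.00,0.00
Dasycottus setiger,Marine,Benthic arthropods,Invertivore,0.04,0.00,0.00,0.72,0.10,0.10
Enophrys bison,Marine,Benthic arthropods,Omnivore,0.11,0.31,0.00,0.54,0.00,0.00
Gymnocanthus galeatus,Marine,Benthic arthropods,Omnivore,0.27,0.00,0.08,0.38,0.05,0.09
Hemilepidotus jordani,Marine,Benthic arthropods,Omnivore,0.10,0.05,0.02,0.53,0.00,0.22
Hemilepidotus zapus,Marine,Tentacles and appendages,Invertivore,0.20,0.04,0.44,0.11,0.00,0.08
Hemitripterus bolini,Marine,Squishy swimmers,Piscivore,0.00,0.00,0.00,0.00,0.00,1.00
Hexagrammos decagrammus,Marine,Benthic arthropods,Omnivore,0.13,0.10,0.00,0.52,0.00,0.24
Icelinus filamentosus,Marine,Benthic arthropods,Invertivore,0.00,0.00,0.00,1.00,0.00,0.00
Icelus spiniger,Marine,Benthic arthropods,Omnivore,0.00,0.00,0.00,0.87,0.00,0.11
Jordania zonope,Marine,Benthic arthropods,Invertivore,0.19,0.00,0.00,0.51,0.22,0.00
Leptocottus armatus,Marine,Benthic arthropods,Omnivore,0.00,0.00,0.00,0.65,0.00,0.35
Microcottus sellaris,Marine,Benthic arthropods,Invertivore,0.03,0.00,0.00,0.75,0.09,0.12
Myoxocephalus polyacanthocephalus,Marine,Benthic arthropods,Piscivore,0.00,0.00,0.00,0.77,0.02,0.15
Oligocottus maculosus,Marine,Benthic arthropods,Invertivore,0.03,0.00,0.00,0.88,0.00,0.00
Oligocottus rimensis,Marine,Benthic arthropods,Invertivore,0.00,0.00,0.00,0.79,0.21,0.00
Oligocottus snyderi,Marine,Benthic arthropods,Invertivore,0.14,0.00,0.00,0.67,0.03,0.00
Orthonopias triacis,Marine,Benthic arthropods,Invertivore,0.38,0.00,0.00,0.62,0.00,0.00
Porocottus camtschaticus,Marine,Vermes,Invertivore,0.82,0.09,0.00,0.09,0.00,0.00
Psychrolutes phrictus,Marine,Benthic arthropods,Omnivore,0.01,0.00,0.04,0.94,0.00,0.00
Rhamphocottus richardsonii,Marine,Benthic arthropods,Invertivore,0.07,0.00,0.00,0.62,0.22,0.00
Scorpaenichthys marmoratus,Marine,Squishy swimmers,Omnivore,0.04,0.00,0.00,0.37,0.00,0.58
Triglops scepticus,Marine,Pelagic arthropods,Omnivore,0.04,0.00,0.00,0.11,0.70,0.12
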