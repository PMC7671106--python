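item,chitinous_exoskeleton,calcareous_shell,internal_bony_skeleton,sessile,demersal,pelagic,fossorial,worm_like_body,body_segmentation,animal,capable_of_swimming,fast_swimmer,high_lipid_content,difficult_to_digest,defensive_spines,defensive_pincers,herbivore,detritivore,carnivore,planktivore,multiple_appendages,complex_eyes,cephalization,substrate_gripping,stinging_tentacles
Algae and plant matter,0,0,0,1,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,1,0
Anemone,0,0,0,1,0,0,0,1,0,1,0,0,0,0,0,0,0,0,1,1,1,0,0,1,1
Barnacle cirri,1,0,0,1,0,0,0,0,1,1,0,0,0,1,0,0,0,0,1,1,1,0,1,1,0
Bivalvia,0,1,0,1,0,0,1,0,0,1,0,0,0,0,0,0,0,1,0,1,0,0,0,1,0
Copepoda,1,0,0,0,1,1,0,0,1,1,1,0,0,1,0,0,1,0,0,1,1,1,1,0,0
Crab,1,0,0,0,0,0,0,0,1,1,0,0,0,1,0,1,1,1,1,0,1,1,1,1,0
Crayfish,1,0,0,0,0,0,0,0,1,1,1,1,0,1,0,1,1,1,1,0,1,1,1,1,0
Ctenophora,0,0,0,0,0,1,0,0,0,1,1,0,0,0,0,0,0,0,1,1,1,0,0,0,1
Cumacea,1,0,0,0,1,0,1,0,1,1,1,0,0,1,0,0,1,1,0,1,1,1,1,0,0
Detritus,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
Eggs,1,0,0,1,0,0,0,0,0,1,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0
Euphausiidae,1,0,0,0,1,1,0,0,1,1,1,0,1,1,1,0,1,0,0,0,1,1,1,0,0
Fishes,0,0,1,0,1,1,0,0,0,1,1,1,1,0,1,0,0,0,1,1,1,1,1,0,0
Gammaridae,1,0,0,0,0,0,0,0,1,1,1,0,0,1,0,0,1,1,0,1,1,1,1,1,0
Gastropoda,0,1,0,0,0,0,0,0,0,1,0,0,0,0,0,0,1,1,1,0,0,1,1,1,0
Hermit crab,1,1,0,0,0,0,0,0,1,1,0,0,0,1,0,1,1,1,1,0,1,1,1,1,0
Insecta,1,0,0,0,0,0,0,0,1,1,1,0,0,1,0,0,1,1,0,0,1,1,1,1,0
Isopoda,1,0,0,0,0,0,0,0,1,1,0,0,0,1,0,0,1,1,0,0,1,1,1,1,0
Larval fishes,0,0,1,0,0,1,0,0,0,1,1,0,0,0,1,0,0,0,1,1,1,1,1,0,0
Leech,0,0,0,0,0,0,0,1,0,1,1,0,0,0,0,0,0,0,1,0,0,0,1,0,0
Mysidae,1,0,0,0,1,1,0,0,1,1,1,0,1,1,0,0,1,0,0,1,1,1,1,0,0
Octopus,0,0,0,0,0,0,0,0,0,1,1,1,0,0,0,0,0,0,1,0,1,1,1,1,0
Oligochaeta,0,0,0,1,0,0,1,1,1,1,0,0,0,0,0,0,0,1,0,0,0,0,1,0,0
Ostracoda,1,1,0,0,1,1,0,0,1,1,1,0,0,1,0,0,1,0,1,1,1,1,1,0,0
Pelagic amphipod,1,0,0,0,0,1,0,0,1,1,1,0,1,1,0,0,1,0,0,1,1,1,1,0,0
Planaria,0,0,0,0,0,0,0,1,0,1,0,0,0,0,0,0,0,1,0,1,0,1,1,0,0
Polychaete annelid,0,0,0,0,0,0,1,1,1,1,0,0,0,0,0,1,0,0,1,0,0,0,1,0,0
Pandalid shrimp,1,0,0,0,0,0,0,0,1,1,1,1,0,1,1,1,0,1,1,0,1,1,1,1,0
Sipuncula,0,0,0,1,0,0,1,1,0,1,0,0,0,0,0,0,0,1,0,0,0,0,1,0,0
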