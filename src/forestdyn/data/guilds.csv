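species,family,guild_code,guild
Amaioua intermedia,Rubiaceae,Sb,shade_tolerant
Copaifera langsdorffii,Fabaceae,Sb,shade_tolerant
Croton echinocarpus,Euphorbiaceae,Pion.,pioneer
Faramea latifolia,Rubiaceae,St,shade_tolerant
Myrsine umbellata,Primulaceae,St,shade_tolerant
Pera glabrata,Peraceae,Ld,light_demanding
Protium widgrenii,Burseraceae,Ld,light_demanding
Psychotria vellosiana,Rubiaceae,Ld,light_demanding
Siphoneugena densiflora,Myrtaceae,St,shade_tolerant
Tapirira obtusa,Anacardiaceae,Ld,light_demanding
Cupania zanthoxyloides,Sapindaceae,Ld,light_demanding
Eremanthus erythropappus,Asteraceae,-,unknown
Eugenia acutata,Myrtaceae,St,shade_tolerant
Miconia sellowiana,Melastomataceae,Ld,light_demanding
Myrcia splendens,Myrtaceae,Ld,light_demanding
Prunus myrtifolia,Rosaceae,Ld,light_demanding
Rudgea jasminoides,Rubiaceae,St,shade_tolerant
Vochysia magnifica,Vochysiaceae,Ld,light_demanding
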