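# Synthetic default trait table: representative values assembled from the
# coral-trait literature (skeletal density g cm^-3, vertical extension cm yr^-1,
# morphology coefficient converting planar cover to growing surface) and a
# default parrotfish bite-rate constant. Not measurements from any single
# study; replace with your own table for real analyses.
taxon,morphology_m,density_d,growth_g,brc
Porites_rus,1.4,1.30,1.2,
Porites_cylindrica,2.0,1.22,1.8,
Porites_lobata,1.0,1.30,1.1,
Porites_lichen,1.3,1.25,1.0,
Porites_massive,1.0,1.30,1.1,
Montipora_encrusting,1.0,1.52,0.6,
Acropora_hyacinthus,1.5,1.60,3.0,
Acropora_branching,2.0,1.49,4.0,
Goniastrea_retiformis,1.0,1.45,0.6,
Pocillopora_damicornis,1.8,1.45,2.0,
Favites_massive,1.0,1.42,0.5,
Chlorurus_spilurus,,,,20
Chlorurus_microrhinos,,,,24
Scarus_psittacus,,,,18
Scarus_rubroviolaceus,,,,21
Cetoscarus_ocellatus,,,,22
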