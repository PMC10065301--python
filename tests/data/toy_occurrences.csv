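species,longitude,latitude
synthetic_species,102.25,22.25
synthetic_species,102.25,22.25
synthetic_species,102.25,22.75
synthetic_species,101.75,21.75
synthetic_species,102.25,21.75
synthetic_species,101.75,21.25
synthetic_species,101.75,22.25
synthetic_species,100.75,20.75
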