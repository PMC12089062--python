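parent,child
distance,pop_density
distance,forest_cover
distance,fragmentation
distance,morph_abundance
forest_cover,morph_abundance
pop_density,building_density
pop_density,speed
pop_density,traffic
building_density,crossings
forest_cover,crossings
fragmentation,habitat_split
speed,mortality
traffic,mortality
crossings,mortality
habitat_split,mortality
morph_abundance,mortality
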