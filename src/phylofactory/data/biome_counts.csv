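# Reference compilation: globally listed alien grass species per source
# biome (total, naturalized, invasive counts).
region,total,naturalized,invasive
Desert,126,42,11
Mediterranean_shrub,137,63,25
Montane_grassland,73,3,0
Taiga,63,2,2
Temp_broadleaf_forest,393,211,138
Temp_coniferous_forest,76,18,5
Temp_savanna_shrub,159,33,25
Trop_coniferous_forest,19,2,0
Trop_dry_forest,9,3,1
Trop_moist_forest,125,61,29
Trop_savanna_shrub,159,40,25
Tundra,16,2,1
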