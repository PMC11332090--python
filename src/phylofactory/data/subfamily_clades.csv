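# Grass subfamily -> major clade grouping used for subclade analyses.
subfamily,clade
Bambusoideae,BOP
Oryzoideae,BOP
Pooideae,BOP
Panicoideae,PACMAD
Arundinoideae,PACMAD
Chloridoideae,PACMAD
Micrairoideae,PACMAD
Aristidoideae,PACMAD
Danthonioideae,PACMAD
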