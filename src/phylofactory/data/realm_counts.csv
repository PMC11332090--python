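# Reference compilation: globally listed alien grass species per
# biogeographic source realm (total species attributed to the realm,
# naturalized and invasive counts). Used for worked ratio examples.
region,total,naturalized,invasive
Palaearctic,378,193,122
Nearctic,245,109,26
Australasian,270,64,42
Afrotropical,150,45,23
Indomalay,57,33,17
Neotropical,120,35,15
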