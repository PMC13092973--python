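>synthetic_ES_selfcomp_24nt SYNTHETIC stand-in: 24-nt stem-loop with a fully self-complementary terminal loop
CCCCCCCCCCACGUGGGGGGGGGG
>synthetic_ES_selfcomp_20nt SYNTHETIC stand-in: shorter self-complementary-loop hairpin
CCCCCCCCACGUGGGGGGGG
>synthetic_ES_selfcomp_16nt SYNTHETIC stand-in: minimal self-complementary-loop hairpin
CCCACCACGUGGUGGG
>synthetic_ES_control_24nt SYNTHETIC stand-in: control hairpin, inert (non-self-complementary) loop
GGGGGGGGGGGAACCCCCCCCCCC
>synthetic_ES_control_20nt SYNTHETIC stand-in: shorter control hairpin, inert loop
GGGGGGGGGAACCCCCCCCC
>synthetic_ES_unstructured SYNTHETIC stand-in: no pairing capacity at all
AAACAAACAAACAAACAAAC
>synthetic_ES_mixed SYNTHETIC stand-in: generic stem-loop, weakly self-pairing loop
GGCAUCGUAAGCGAUGCC
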