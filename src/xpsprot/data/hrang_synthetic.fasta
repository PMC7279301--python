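>hrang_synthetic synthetic stand-in for the ZZ-angiogenin chimera (GenBank M74186 + AAL67710 unavailable offline); 8-aa leader + ZZ + angiogenin region; 247 aa
MKAIFVLNNRDQEAPDGLQEELLKLSPEADGGNNLGLGFHYKPILKSGDKEAYAEPKNRQ
KKHQLGQQQNEWRENTFIFDVEEGFALNAISQDHLISNSSKKQFAKAAAAVDNSMMTQVP
TNIALAYLDTGYTVVFIVNRIIRGPGYFDNRLPGSEDHDPIKNHPKITKGGENLSRTGGC
GDSLQRGHANTWTAWHIRLSEQQSGAVFRKKVAKHKRMRNGHTNVSQPCCCSPGREFCCR
LFYQFPS
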