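>apoa1_synthetic synthetic stand-in for apolipoprotein A1 precursor (GenBank AAB59514 unavailable offline); 267 aa
LDEFMWPQGKRKSNYLQIYDKAKPHAAKVADLQEEEGRLLLLNDEMDRDKYNLASELALA
QYGKLWSRTKEVVAEAQQPALGVESEARGAGNPGLNQVFGQTTGEGKLLLLGTKLEYKGK
KTESKAQLKPHLQKSQSGSLQVDEPLTREEDAHSLEAFQLFLHRDRNSEVWGLFREADPE
GILDGLRESLAQQQEGNWSHKRFAGVIKLVKDFTETVRLDLRKERLSQYGVLTRKAKAPK
GVPNYGDDLERSAMGPEETLVESTPGL
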