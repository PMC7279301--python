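>fibronectin_synthetic synthetic stand-in for a GenBank human fibronectin entry (no accession; built offline); 2386 aa; whole-protein C/N designed to 3.58
FSGKPRGAELMWGQTTGQAPAMSGVDKSPRPAADLETNIVDPVTGAPEETLHGLDKPMKY
MGLCSSPLILEVFKIHHPCTAETFSQVFPFADVSHATKGPSCKPVNMGTKIVTTDILVVI
GTIGIGTATVGNTVTAIYELQRFGIQQEKYYAQVATGISSFTTTPIVPHGSPYTNGLGIY
TEGPTTSNYDDGHWLHDTLRGGIGFKTPLSDHSQYVQPSSNTRTPYGEDLGTPLHIGGSA
TYVNTLIPGGRKGRTGNRQSHTHDQSGGLQRDCHFDYFPGYNVVNIDCFVVFFKDPGGQN
SNPQPVLADDFLDSCLLNAGGYDGTEPQYLTGNTGNIQCGDGGGRIGIDVVLCKQLPPLN
YWKTNGFIHYGQTATPCGIPGPACTDTLVGFPCDGSTVQAVAIRVSSWEVEQSKIWHIRY
SRPQGDTEGSNFKLERALSELESGRPNRDYYYIGATDNETVGPFGTDFWTNDATEPATCA
SGGEIHSPVEEDGRRPGRGVLVQTRKRGDPGSQESCKVTRTQLPGVCMAPEPIRKLHGLE
TIGTQRKRQQTYRTAPNPGSQTTPPQQGVLWEAHRVCLPTQSRTPKQTWHCLFYISSFPK
TDMVLPQFPAMLGSSDISTIQDLPDECTGCTLSVVGSTQEQMSITGEIGSGVEWDEPGGG
ETVIGCTSAVPETTFLSVEIPSAGGSGIQPLGPAEEKSPEPVENQDPGIRPFNYTIDGPN
VKERERTYKLALGCRANNMGVAVLGDDNNVKRALSASGYAGTHTCRGPSCGKCNVSEADQ
LGDGIVTVEISIGPNTTPVITKEAQHGSQLVGRWSIYGSVRGYWGNGKGNMGDSTGELDG
PLGETKVIGYDWSKTAPLYPCAFEEIVPRSLVKIQLPQGIGPRSPSVLEVSTEKSARSQT
PGEAVGAAISTETSRYQQGQDRLSTICLAINSGEKQVGRKHCFATETPDHTLVTLNEIIS
RVYNQPGGETLIDKIPHPSESGNRSPGARPVSIATDCGSSEITKPNTIVVYCEVNPEGNK
IFEYTRTGSEVSAETNEDLTSGQVVNPLEPGWVPSKTRKSFCPKDVDTEIKRTSVGRESS
SREGSTFKPYGEREIYIKYEKTVGQFGDDIVEYLKFLLELGTSYPPEVGFVANHLEECTV
CDPSCEGSSTTDGLGITPVVGGGRDLEIGYSKNRRSWNDKPRLRTITRCEDTCGRGPPAV
GTTSVGYYANYVEEVLYVSTFLPGGPGEVTLFNVGMCYCGTPPSSQKLQDAFQAQKGLDG
RKYSNSKNIRRYLRIEQITRTQGTWWRWPTGVGGPERYVQQIPVAPVTEFYEGQEWDNGS
RLWKGEEYPDSDRQGQKGYLHGECPRGQEQISVVILTAPTPKEMRPMIFYGPLTRKGSPS
VGRTYLKYDTVPDPPFREGGNTRQALKETACGGNTGIPGEAITLSDETIWQYVNGEYVKW
RVRSIQPTIGNTLKYMLVQVDIDTHPPADDGVGWESECVVDFPNGPEGLCRPLGPEFGAG
GPTNALNPNVSVIVGSRSGSYTLGSKPCTESGPVEGTPSKNISFVPFVPSQVPRSKTPDY
SGCTHVIGFTDLRSSPPSDSKMSHSGVGTSGTGCKTTKTMCRRDTWNWGVNGFGSQYKMY
VAPHRSYTDEAHGVTWGSSYAITQGKSQKGPGCTVCQPNNGGTSGTGGQHSRVDDWDSQG
TLFMDTGVGLGPTGITQRNDYCVTIREVIHSTTIVGFVLGVGFPWNMDPDYTEVTPKDYP
DPIFVPYYWVGTNRRGVGLEYRCNNAYADLCHDARASGLTYIPRGPESNSTSVSEGKEPE
GTHFSFILAPTGGQCVSQISYTDSETFKWPKNCFGWVCVSRGDAGDYPPENSWGPKSYAY
GFLGWTGVFFYRGQTESEYFTHTLNGRFDDSQGVDSVRLETYPNVVGSQIGPKNFFPTDT
GPWVLTNGPTVHHLEATGNSVDTNGPLYNLQQPETYKWVQWSRQDHHQVLGVSVTHGGHY
GPRFCFDILGGWVYESIGSGQPADYSGHVIGEDWTNGVRPGSDQRGDAYHSNRRDYFGGD
NTHKHPAVDKKWAPVISRGSSLSPDPELDGPSGNIDTKGDRGVGFPAPQSEKTGNGNHQV
SRVFNSTGTVRICTCGGTNSWPGRENEPGERFMGGGGIKRTPETLYGRTICFAVGNRKVY
KEDGNRPLEGTPSLTRTCAVGAAANKQTDTFIIYSQATTRNKLTSGLISFPVTKESMGYF
DSGYGSFMGSVPETEVAVAFRLSHDWLWSSSPYGTGGGEWWEGSCYPFNESRPEGDQITG
VGVVSDRAQHEWKLTGGSSSPTVTWVSGELVEGETEVRSKGAEAAWSTRLSGRYGDWYKL
STPDNPKYCEGGATKGRISKKAENITPWIDCAGKMDEVGGYNTLSQ
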