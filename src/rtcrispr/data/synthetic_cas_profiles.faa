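>RT synthetic consensus profile
WPQVNSTFCHGVWALTDSDLTHHGRGYKLMNNMYTSRPHYLFTEVPDAKADMYLTWTPKM
GLIFYACEYQVFRILAPTQEMGYVEMWTRPARLCFMRMPVQIPNDCQINHFEITKINYIN
KPKPMQYENKIFCKTCKYYFAQAHLVCQMDTTLWPWYNGDNESWFNAEIVYPNNCIYKFF
RAYVNLSMLHKSCARITAWDKYDQRKCMKVQHCNGQVIWMMSSWYEKWHANSRTPDTKTT
YAVPLSYMCRFFEEWIDEIHHWVNYHDGCYFKFYEMYMVVSRNNTKWVIKRWCCFKEMMY
RGSTQQHRDPWYGHPIRFECLFGWTTNDRPWLENLQIHDYSLFPKPCERCQKASQTVRTD
WWQTRVVMTWGAEAKAGGRFWEYNFAHNDEDQCALHNWVMPTKQFPFESNIAFTLYWVAC
>cas1 synthetic consensus profile
LREQDIDAHYNRFFWRLGVLCVKKIGPHMCTFPGEERCSLLFIRVWPGCNNMMCIDVVTL
TTHCTNKVYVAALMFINSSCIGGTKLYLSYYHKARIAEECCNFYNNMPSHPNQSSNCTYN
KELNSLEEMPVTNDTMTRHKKGSIQMKQENDDTTQWPDIFREPTEWRAMHQELLLWWCSE
ELYMNRLKQDVINYSSTDKTGHVSGALVMELLPQFMLELDEGYCVFWDPLFIKNRGIAGH
TSSGFKKSVKFVMWIHCRLGKDYKHPSWQDKRTLVDHYEQFDEWYDRCTH
>cas2 synthetic consensus profile
AWWAIWIPVCLNWLTNKRTQPYPEWTIKQSRVCYLGFLHWLWQIKWQKRIFSCLKKFIDK
RDECTSANLQITMFMFMGKHMSQILHHPSEGDYQESHGLP
>cas6 synthetic consensus profile
IKEQHCMGRASMRIVMYGVQWEMWFYYLRLQVRGNTNGSRPHNPFWNCGTQMLIWITCMG
KPCCNQCYKYDVPTTEEYKFPVGVCPIMPFAMYGNDHDDTWWRDWAGGRDYEVNGKDKQF
YQIGSIWLRWYFKRKHPVLISMHVPQTCVDAYGARHKYNAQEHFWCMLNNDHNDTTMTKN
LDEMCPHKVVLITMRDRNFSMRTGTYMRSKTKVSMETPNRYMIVPLELWGYWTHSQVKPW
>cas10 synthetic consensus profile
HHPPALINPACLTFDIGCWQSVPIADHPQDGVGDFILLDDFHYGIRHYLISSQDGNIKGG
LTIRYDWGCTAYFPFVRYSRWPFFQISPAWYHGITAEQKKWSDFGQKQFLIEFKQRSENC
DLQFETNTCWTTDPMEWTTRERLQNTMGQQGMQHEHTEILSIYKLVLQIQNYIFDMMCAI
AYSCSSRVRMRSNKNIKMREKHEHHYIHIFWWIDAYTVNPSKTEKDSDMHYKDWNMPYAR
LDWNWEQAYWVHQETDRQGLLACRQGKSQLVMALFQDYPSLCKLKFFDLEPFKYMRQVCQ
FHWIMKDGEKASMCYGHLMQMPHRVDDEHHSGVSWYCQVAEGFTDWINKHVIYPIVGHVE
VAADPVTPPYWCNIDSMQMCVKFPHQMLCEVYNLERPMGCYFQCQEQFLKMHHIPTIAED
PTFMLKVGPMVFWVKTPHVADVSGYQFVYSPVTLSTALWGPLNHPSRTGDMEPIRLNYPW
FYFRAQVGEICAKTKGFCIHKHNRAAGFCVCVCPINMFDV
>csm2 synthetic consensus profile
RSPMVEPFQIKHNCSKYKDGLIGHRIEPRLREDSSMLLFRISKTTTGQSRVEQQIGNGND
IIRAIQLRVSHDCPDTNASEYGNLIECMYHHQYMYQSFNRIRIRLCCWPNSGIKQMGMIF
EGMIKSQKNA
>csm3 synthetic consensus profile
LAYACLHHWKCLGLTWRWFHSGNQHEAKKRRALSYRGIIFAMGGITRNRHITPPFDFKGL
GWYHRKSYTKLTICIICEIVKNHFECCKNCWLVRKHGEMILEQTNCERHHYRKSGDLSGW
HNEPEHCEDRRTHFEDCIDPNIDYFSWWNNTSQYFANNVECSWFFRPHPQCQPWEVRKAQ
YEDCFRFWVRAMFPQRQNTIVVCINWYSCSCTRYTYQMFIARLYYPWAKA
>csm4 synthetic consensus profile
WTEPNMALDSADYHWCSQYKVVLHRWSHDWYVYGIMGCKPDQKLWKELFSKEITNRNIEY
DNFMWMSHFMLCGPPHEQFPEYVRTAYDLLQMHLKRRWPCWPSGQITYYCAFRMMRMYRY
DWPSHLPGTVCRPRVSEWLMCGKADFSQRIPERDEARNCQNYDSVENFWYRGMMGTKPEA
NLWMVMGDRYMMAQRSTGKAWPTWSVCVMFMVECSGATHCTSYSQWCVQRVESDLCKHMH
EYIVCCDLMTPIPMAVQWNEATKKVASHHVVEEERYQKGWTGMCEWPHEWFQPTPHIRNT
>csm5 synthetic consensus profile
EKVGKLAECQIMHEQCYNFYCYVYFKIWLDNAQDFACDRLSTRRVMECAPNPFTVMEHHG
ELGGSYPCTQTIWKQMIHPRNPALKKHNYRSEHDYERIQMKKTSHQGQKMGYHAHLNITY
MHMKRSEKYERFIMAIENIFQYYHFIYPSTKVYMKVDQDHYLTHISANCMCHARRGFHMA
PDEHSHRKAQTGSEIPQRGWHMYCVHGQRIVDMYHTRGIDVLYFAMVRVGMIVPVMLAVH
MDRVRLWSEGKCIVKVNNDDYCYQVMFHWNRCMFMYVKTKMYIKFAMQMMDGRMWGLRPY
ECQRGVHRYNPGTILDVCDRCDKAWFEAGNIMGKGCDMFQQHCGWKSGTI
>cmr1 synthetic consensus profile
YNMAVGVDAFATRIHLTHWYLVSCLGSKNSWHEERDFTPIVHKKQYFRKFHEEDYWSLYQ
SVHCRFYKASLKPHSCSKMECYGVWKWCLIDYAPILPIMEPDQKIYPWAVTHQNCECGTE
DIKCLVEWNEIHAFKQKYIWYAMWFLIEFHLMNIFPHCKPTHFTMPQCDYDFRNSIKNGD
KGNFAKDIYISIDILTALMPINHNKVNWEADKDYSFEMAIEPISIPNFRPIRPDGPYAQK
MHGECQKQVPFQRRWNQYCNQMRSYGYYNPEHEGFHGYTHPDDVNELHLHEEFEYVLWDA
SIRVYGPAYVLSTAMRRKKPFEIHHYQKWITVQPVLWAFRQGPHEFLKMVSMSTVYDRVD
GFGAQTMEPTLFSVHCQSKWDLFHINSWHD
>cmr3 synthetic consensus profile
WKGDQTRPDNGFSQRFFVVDTVDAQVWFFCQETSESTDKITFWRSPKWGQVNRWMFTCWI
WQPFFTWGHDVVSFDEMRISRMPISYMAGPGFRKTINIQGDRNNWVMRPLQNSTLDPAHM
RLGNMMWFTWGYEFVICWTNENIVYEQDIQPKRFQEYFVWTIIDFHPEIWFGIIGIPADN
VHCTKITHTFKLFWKYQLHTFFAVANRHWRWNKKGNRYFHFFLPWPCFHHIKNGAAYAPG
GWPNWWSMINRKFRGPECGICMYMFAHHHRHKTSMGVQPAFSLNEYDNFMCEAVMENKAY
ADPVQQCDVQRPRYSWWDGYVDVTLKEVRLQAQWKHGRRV
>cmr4 synthetic consensus profile
CQTPPLRHFYLGQHHDYEFHWGIISDSPQRVAEMWVGCQFHNLDSGAIFQSQWFDSMMSI
IVFEDDRRYEMEDKADVPNPGDGCYFACGYKQMQVVVRLPFEGQGSGENCKETQVKIMAS
EWTQNLCNRFRNARITQPAYSNRVFDLQPMDFVFYSDLNDRYFHLKAFYLFGFWKWNSEL
VNRQTRDKCMINDPAEMVQIDPPRIKRGENDCKHELCVKKHSIHTNITMVVVVVPFINKD
FVPLEEAVRLWSIEKPTMQPSMELRGNFWTKRTFTKMPIFRQWQCQGGIQADGDFNNFNH
>cmr5 synthetic consensus profile
IDRVHPEETLLNCRMGTRRIDFPIKTVGRLPWISFQDKRATRSFWIKQYQQSVDYTWQYL
PCNFHGNYVCVRTYHLDSHHSPTAEDREERNCPILFDACYIAIYATTIENVWKESMPMLR
YHDCDMPQDPTDAMRLQVPDTRVSIWCNWRNDSIPGFENK
>cmr6 synthetic consensus profile
VFYATPSGGSCGQAHWVGDMGSHHQQVITTWPAESTGTMGKQWTRYASSFSDETIVDVYL
GSAQELNKFYILNQWTINKKKLMHKFAVVFRSGQRICENTFVFRWWDNEVKPLSQVPGDK
SKLRPQCNNNNSHWPIMEECYCIYQCPKSMQSWALLLAMEPHEAKGCSEPIYSVNTDLKQ
WSPHKMDNHFANKDSQDNANENFGKHCCLTIMRDDFQTNGSGYDHSKFWFVQKLGTRNMK
RYPHQDRCAYWHGMFLPYNKKSETQAWITHKLNYESVGWA
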