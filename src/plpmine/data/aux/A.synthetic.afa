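>A_seed1
YKSGNKFVNLSEGCDESRAFVDQQITIITQQRPMTMCQQNDPYHTSFMTAEADLTGCGIKWSNLRGMRNI
DNWRPQLQRFEKTVTQAGFKGQCMREVSNGSEAVPTPLAPLMTNTYNYDEKHGGPEHIDCRYVQIGWERK
KDAMSINGHMGIFAPHAAEKRGSCPYRRGGQRHVPSLEPDGAAGVEGYVPRIIYGNQMDDFMVGDVMATT
IAGIIVRFQEQGERSNDILLLFGPGYWSKSPILIKEYLKMMEKQLAAMALDASCMVTFILIINPRGEVAT
GMPKKRGGACIAGVEPHAGRGKLECTPDKSPKIKQRPLGQINYGVCDTSVGAPPSAKARGATIWLPVCIQ
AELEWKALSVVKDKKVTTIPAQLGLASFQPVIISIRIEGARESGALVEGAHTTRMTSMAALAIDLGLDAN
PEVLASLEYSLAPNLFTDSETVEKDIDNELLEMTFILNRVGYYDEIKSVRGGKSEKDVRDHVDVAFPASD
PAEKFNTIYY
>A_seed2
YKSGVDAVNLEEGIDESRPITTQLITINTQQRPMTMPLQNDPVATSIFTLATDLSGIFVKPSPLRAFVNY
DNNWAQVQRFEKTVCQAGFKGQCMEEDSNGSGEVPTVTAPAMLVTSNYFERHGGPFDDDCIYRAIGWEFR
WHAMYENGHMGITAPHLAEFRGSHPYRSGGQRHVPPLEPDGAEGVGDYAPRRIYGNQMDDFYVGDNMWFL
FIGIIQRQQEQGEQSNDIGLLFGPRYQYTFPILVKAGLKMMERQLAAMELDASCMASTQLNFYNRDIVAS
GYPKLGEFCGVHGVIPAEGRGKDEHVPHKSPRIRHRPLGQINAGVCRRGVGAPPSAKHRRDTQQLSVPTC
EALEGDALSFVWDKKVTFIPYGLGALSFQPVIKSIRTIGARDSGALVEGEHTTRMTSMAHLGIHLGLFAI
PINLANLAYSAQPNRFTRSELLEKDVDNELLAMTFQLNRVGYYDEFCYRRGGKSEKQYIRHVLVPTPAED
PAEKFNTVYA
>A_seed3
YKSRVRAVAASEGVDESRMFTTQQITIITQQRPMTFPLQNDPYATSIFSAATLLFGIGKKPSNAIGMINY
DNNWSQVQRFAKTVAQAGFKGQCMIEVSNGSEKTPTPLAPLFLSTSNYFEKHGGPFEDDCIYVAIGWATR
WQEMSENGHMDIQAPHAGIMGGSHPYRVGGQRHNCDKEPDGWEGVADYAPIRYYGNQMKDGMNGDDMATQ
GFGVIVRQQEVGEFSNDIGLLFGNRRVYFYPILIRHGLKMMAKQLAHMELDASCMASTQLNINNRDEIAT
GYPKLAFGAIRHGVEPAEFRGKDECKPEKSPNSRQRPLGQFNNGVCDYSVCAPPTAKARGDFQVLSVCIC
EALDWDALSTVKDRKTTTIPAQLGAESIQPVIKCHKTIGARQSGALVEGAHTTVYTSMALAAIHLGLFAF
PENNISLAQSLCPNRFINFELCDKDNDNELLAMTFGLNTVGYYKEFNMALGGKSEKQYRRHVLILTPAIE
PFEKFNTVYY
>A_seed4
YKSGNKAENLSIGVDESKAFTTQQISIVTDQKPMTMCLQNDPSATSITTHATDLTGIFNKPYRLIGMVNY
TNNWSQVQRFEKTVAQAGFKGQCMIEVSNGSEAVPTPLAPLMQNKSNYFEKHGGPFEDDGIYVAICWERR
WHAMYANGCMGIFAPYQEEKRGSHPYRVTGQRHVPPKEPDGAEGVEDYAPRFIRGNDMGRFMVGDNMATL
IFGIIVRYQAQGEGSVDIGLLFGPRSQYFSPGQIKEGLKMMEKRLYARELIASCMATTQLNINNRDAIAT
GIPALGFGVGVHGIEPAEGRGKDELIPAKSPKIRQRPLGVENAGVCDKSVGAPPSDKARGDTQYLSVCFC
AALEWDALSFMKDKKVTTIPAQAGAASIQPSTKSRGSIGAIDSGLLVEGLHTRRMDSMAALAIHTGLFLF
PENLLSLAYSLQPNRTTNPELLNLDVDNDLADMTFGLNRVAYYDMMNYERGGKSEKQYRRPVLVAFPAID
PAEYMNTVYR
>A_seed5
QKSGNKLVNLSEGIDASRYFTTQQVTIVTFQRPMTMPLQNDPSATSIFTLATELTWIFNKPSNLIGMVNY
DNNWSQVQRIEKTVAQAGFRGNCMIAVSNLSEADPPPLYMLNLNASNSFEKHGGPFEDECEYNTTIWARR
WHAPYENGHMGIFAPHAIAKRGSHPYRVGGQIAVPSLEPDCAEGVADYAPTKGYGNVMDNFMIGDNMATL
IFDIILRQQEYGEGSNDVGLLFGPGQQYFSPILARQGLKMMEKQLEAMELDATCMASTILWINNRVLIAT
GYPKLGFFLGIAGVEPAEGRGKDECIPIKSPKIRERPLRQSNAGVGDRSVFAPPSARDLGDTQQLSVCIC
AALEYDALSINKDRRVTTIDFHAGTSSEQPVIKSIGTDGLKDSGALVEGAAESKMTSMAALAIHLLLFAG
PENGHVLAYSLQPNRFTNSELVEKDVDNELLAMTFGKVRVGYYDEFNYARMRKSEKQYRSAVLGDFPAED
PLEKFNQVYY
>A_seed6
YKSGNEAVTLSEGVDANAAFTTQQVTIVTQQRPVTMPLQNDPYHFSIFTAAFDLTGVFNKPSNKIRYVNY
DKNWSVVLRFEKSVAQAGFKGQVMVEVSNGSELVPTPLAPLMLNTSNYTEWHGGPTFDDGIAVAIKFEKR
WHAGYENGHMGIFKPHAAEKKGSMPYRVGLVRHVPSLEPDGAEGIDDCAPRILYGNQMDDNMLGDNMATL
IIGIIVIQQEQGEGPNEVGLLFGPRYQYFSPRLIRDGLKFMERQLAAMELDDSLMASTLLNIFNRDEILT
GYPKLGKGKGIHGVEPHEGRGKAECIPEKSPKIRTRPLGQINAGVCDRSVCLPPSAKARCDTQEKYVCIC
AALEWDALSFVKDKKVTTIPETLAASSIQPVIKSIRFRGARDSGALVEFLHTSRMKNMAELERWLGLFAF
PENLASLLYSLQPDRFTNSELCDKDVDNELLAMIFGLNRVGYYDEGLYARFGNSEKQYERHKTVETSAEE
PGEKFNYVYY
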