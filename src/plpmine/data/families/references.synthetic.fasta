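>Aminotran_3_ref1
HREHEKTTAVDIYSPGRLLDSSFAIDEIEIDKLRGTTAPAKLRFMLGDVDYNVSTSDPGYEVLPNETLFC
VGRLLTYLPRRAMCLLAQCYKKNLVLQETVRHGREIGAYIKLKAALRLDQANQIPLLYPKGWSVTAESWM
IQAKAYPFQYFSHGLLKNTLRVTISSSLEIVGVLYLDAMGQVTAQEPDHWLGTGLLRKCRIVSDDAKDVD
SKNDDAEHRSLKLIILSFQDKSLSVFGQVFEPVNKCTENGFHELLNDAVIADVADVVWNLHSGKMKSSKY
KLTSNAQVHVRGSEGPVATIGSKLSILQHLESIEKESPSLQYLSLITSPIYVAVILTGMTSNSRHDWDSG
VWMSNGTNSSCYMVAWGKIDAAWWAYPIIVLVKKLAHVMHASNKPPDLPFLCDKILSRFSNANRSIMKND
PENTRQMT
>Aminotran_3_ref2
HRIHEKTTAVTVYSPGRLLDSSFANDEIEIDNLRSTFAPAVLRFMYGDVDYNVSTSDPGYEVLPCIFKHL
VGRLTDYAVIGEMCLLLQLFKDNLVLQEFVRIFLEIGAYIKLKAALRLDQLDQIPLLDPKGWSVFAESWF
IHAKAYSTLYFSHGLLKNTLRVTFSSSLEITGILYLDAMDQVTGQEPDHWLGTGSLRKCRIVVDEAKDVD
PKNEDAEHYSLKLIICSFQDKSLSNNGQVHEPTNKGIEDGNAELLNDTVIADVAVVVLSLHSGKMLSTKT
KATSNATVHVRFSEGNVATRGTRCYVLQHLESFEKESPVLQQLSLITSSIYNPVILTGMTSIEGAGWEPG
VWLSFGTNSSCYMNAKGLIDAHWNEYPIEVLVFKLKHDMLASVVPDPLPSICDKELVKFSNANKVRMRNN
PAAVRQGT
>Aminotran_1_2_ref1
ARIHAQDTAVVRYSPAILLDTSFEVDEFEIDECRLIDWNAQQRFYYEDVDYNVSTSDPNAADDHLFSLHL
KFNFTRGAHIAEMLLLLQCRKKVANCVESVIKTTAIGAAIKLRLALTLDELNWFPLLDPKGWSKVAESLF
ITLDIALILYFSDGNRGNTRIVTFTSSLELVGVLYLDYGDDKTLQGPGHWEHTGPLRKLRIISDDLPGID
PKLMDAEHYSLRLRILVIYVKCLPNNERGHFSKNGGASTINEEAQVDTVVLDVAQIQHAVLPGSMKTTKS
KAVGEQDTHVKFSELVFLFLYTRLSRVLRASYTKKESPSLQYASLIFSSVINPVKAFGMTSQSQGFEESG
NRLSIGTASYGYMYAKGLQECAWKAYMNENLIFQAAWVMAVSYGIVLQPTVIDKWQRYNSNWNDSAKLAA
PEFSDVMT
>Aminotran_1_2_ref2
ARIHALTTEVYQANPAIALDTSFAVDEFEIDEGHFFTQPAVQKFYYEAVDYNHSTSHPPAAVTHCASLHL
PFNLTRGAARLEMLLLLQCRKKNAVCSCSVDKGIAICAYIKLRLALRLDELIWTPLLDPKGWSKVAESSF
IFAKECWTLYCVEGVRENTRCYTFDSSLRLVGILYADYTEIRFLQGYGHWEHTGILRKLRIVSDDAPGID
PKCVVAEHYSLRLRIPVIYVKCLPNVEIQHFSKVAGASTINEEETVDTVVLDNAQIVHDKAPGSMKTTKS
KAVGEQDTHVKFSEKNTLFQYTRLTRVLALSSTKKESPSLQYASLFCSSVENPVDHFGMSSQSYGFAEYG
NWLSVGTASYGYMYAKRLVDCAWKAYMNENLIFKAHWVMACSYGIVGQPTVIDKWLQAFSNKNPSRMCEE
PSFSDVMD
>Beta_elim_lyase_ref1
NWGCALTTAVVKYSPCIATDSSINVDAIEIDICRRTTIPEVLEISYDDVDYNVSTSDPGYIVTLSETMWL
DFRQSTYHPWKEMLLQAQCLFEVHVVQETVDLCIRIGAYGKLRADLISEICRRVPVKDPKDWSVVKESWF
IVYKAYYACYFSHGVWGNTKIVTASSSCEIVGVLSGDYMDILTLLFPFWALGTRGLRDLEIQSDDLHWRQ
PQNMKREHYSLKLIICNVWVGEYPSNCDLLTIMIGGKSNFNEYLLNDTVIADVANIVHKVYRKSTRTTKV
RAVFAQETHVRFSETNVATTHFKLTTLVEAASSKKEYPSCQYASLITSSRYNPVDLIGMTTQSRGNPHNR
VWLSVGTASYCTMYFHCLIDAAKKAYPNEPLVFGLKHNYARSRKIPWDSTVVPYILSRFSDLNDSGMCLN
PPFSDVDT
>Beta_elim_lyase_ref2
VKGGYLTVAVVTYSPCFATPSSIEVDAIEIDICRRTTISRVLEFSYDDVDANVSTSDPGYIVTWNETRWL
DFKVPTYHPWKEMLLCAQVLFKQAVIQETRDLCSDVGAYIKGRAKLRSHTCNRIPVKDPKDWSVVKESWI
IQYKHYYTCMFVAGNWRFTKKNTASVSLEIVGVLYGDYMDFQTLLGPGWALGTRILRDLEICSDDLHGID
PRNMNRDHYYLKLIICNFLVRGSPNNGILLTVMDRSKLFFNEEVRNDTVIADVANVVHDNSRRSTKSTKT
KAVFAEITHVRFEETNVATFEFKLTTLQALPSSKKESPSHQYASLIISSRYPPVELFGMTTLSKGNAASG
VWLSVETASQCTFYARGLIDAADKAMSNEPLVTGLAHNYAKSRKIPKDSTVVEYILSRFSALNDSAMCAN
PPFSDVDT
>Pyridoxal_deC_ref1
GKIHMPTSKVDRSSSGELLGQSFYVDEIEIRICRGTWFPASTKFSTDDVDYNVSSSPCRYAVCGNGLIAG
LVKQTFARPGGEPLLLEQCLKRNAVYFLTVKIGIARGYYIKLRNALGAPILNARPCLKPFGWSIVATRWG
IQLKAYYSASDSAHNWRFTRRHIISSSAEIVGELYLDYEDPQVLQAPGTWLGTYILRKLRIVPIDAHGID
AKPMDAEHESLKLIEHVIYVRLLPHNGILANFRNRGGSIAKRGALNDTVLADVAVRVHDVRPNSDITTGS
KASSHQDTHVRFKETNVAFLGTHQTELVNLSSFKKTSPSLQYAQWITTSCYNAVQAIADTSVSCRGHEIG
PWLSVGYESYGYMAFKVLEDALSGLYPKEDLVFWLALVMMNSWREPTYDTVNPKLLHITSAVVNMGEKFN
PRDSDQSL
>Pyridoxal_deC_ref2
GKVHACTTKVIKSSSGILLGSSFAVDEIEQRFLFGTRTPASTKFYPDDVDYNVSSSNCRSHVLRQRLIHG
VVKQTFYRNRGEPLLLEQCLWKNAVYFVTSKIGVAAGYYIKQRNALGLHILNHKPLLKPRGLSVVATSWG
IQAKAYYSASGSHHVWGFTKKHSITSSAERVGILYLDYADPQILQQPGTWLGTYILRKLRVVPEDAPGID
AKPMDAIHESLKLIEHVIYVRLLPHNGDLAFFRLRGGSIEKGAELNDTVLAAVAVRVHDVRPNSDETQGT
KQVSADDTAVRFAETNVAILGTHQTELVEWSSFKKDSPSLQYAYLFTTSFYNAQYAEAMTSQSRRFDEIG
VWLYVGYASYGYMAAKALEDALDGAIPKEDLVFKLALVMMNSIDESTQPTVVDKLLEKFSNVVDMGELIN
PRDSDLSL
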