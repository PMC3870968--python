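>Pyridoxal_deC_seed1
GKIHAGTEKVVFVTPGILLGSSFAVGEIAIRICKHTRFPASQKNYSDDVDYNVSSSPCRYAKGLNRLVHA
VVKQTFYRPRGEPLLLEQALKKNKVYFYTVKIGIAWGYYIKLRNALGLPELVHKALLKPRGWSVVATWLG
IQAKAYYSASHSHHNDRGTKGHTFLSSAEIVGILYLNGAIPQYLQAPGIWLATYRLGKLRIVPEDAHGID
EKPMRAETESLKLIEHVIYNRLLPLRRKLAMFINKGCTLARRAAQNDTILADVAVFVHDVKPNSDIFTGS
KAVSAQDTHVRFKETNVAFLGTHQTFLVLLSSFKKESPLLQYAYLITTSFYNAVQEFAMTSQSRRFHEIG
VWLSVGYASYKYMEFKKLERLPPGASPKEDLSFKLALVMMNSPKEPSQPTVNDKLLHIQSPVVAMGELFN
SRDSILTL
>Pyridoxal_deC_seed2
GKIHECTTRVDKSSSGILLGSSGAVDEIEIRIGRGTRFPASTKLYSDHVDYNVSSSPCKYLVCGNRLIHC
VVRQTGIRPRKEPLLLEQCLKKAEVYFVTVKIGIARGYYFKLKNALGCPILNHKPLLGPAGWSVVATSWG
FQAKAYYSASGSHPNWFFTKRHTITSSAEIVGFLSLDSPDPQVLQAPGTLLGTAILRKLRIVPIDAHDVE
EKIMGAEHISLKLIEHVIACKLLPANGELATIFNRADSIEKRAGLNDTVLADVAVRVHDVRPNSDTTIGS
KHVSAQDTHVVFKETNVAFLGTHVTRLVELSSGKKESPSLQYAYLETKSFYNEVQAFAMTLQVARFAEFG
VWCSVGYASHGYMEFKILEDYLHGAYPKEDLVGKLKLVMTNSKKEPTQHTVVDKLLHRFTNVINMGEGIV
PRDSDQTL
>Pyridoxal_deC_seed3
GKDHGCYTKIIRTSSGILLGSSFAEDEVEIIICRGTRFPALTKFYSDDVDYNVSSSPHRYAVYGNGLFHD
TVGLTFYDPRCEPLLLEQCLKKVACYIVTNKIKIVRDYQIKLRNALGLPGLNHKPLKRPKGWSVVATTWG
IQAKAYYSASLEFHNWGISKIHLITSSAEIVGFLYLDYFDPQFLQAPGTWCGTYRLGKLRIVPIDAHGID
EKPFEAEHESLKLIEHIIYVRSLPRDLQLAFTRNWGGSIHVRAALNDTVLAIVAVYVHDVRPNPDITTGS
KAVYAQDTHVRKKETNVATLGTTITVLVALSSCKKESPSLQYAYCYFTSFYNAVQKFGMLSQSGGFHEIG
VWLSVGYASYRYMAIKRLIDALWGAYPREDLVFKLDLVMMVNKKEPTFPTVKDKLAHIFSNVQDYGFLIN
PRDSEQTL
>Pyridoxal_deC_seed4
GKIHACTFNHIRSSAGILLGSSFADDEIAIRICRFTRFPHSTKFYSDEVDYNVSPSPCGYAVCGNKLFRG
VVKQSFYRPKGEPLLLEQCLTKNEIYNVTVKIGIYRNYYTKLRNALRLPRLNTRPALRPRGWSVVATSWG
IQERYYYNASGSHHVWGNTKRHTFTSSAEIVGILYTDYADPQILWCPGTWLGAYILRKLRISPIDAHNID
EAEMEAILEVLRLIEHVRIVRLLPHNGDLAEFCKILGSIEKGLELNDTVLADVAVRNEDRRSNSDITTGS
KAVSAQDIHVRFKETNVAFLETHQTILAELSSTRKESPSLQYEYLFTTYMYNAIQAIAMTSFSSRGMDIG
VWLSVGSASYGYMAFKRLEDAWWGAYPKDKLNFKLALVFMNSKRIPTQPTNPDKLLARFSNVPYMPELIN
PKDSDQRQ
>Pyridoxal_deC_seed5
GKWHALTTTVIKSYSGRALGSSFAVDEIEIRVVKGTRFNASTKTYSDKCDYNVSSSPCRYAVAGNRLIHG
NSKLTVRKPRGEPLLLEQCLKKNAVYAVTVKIGIAKGYYIKLRNALPLPILNHKPLLKPRGWSIVATSWG
IQAKAAYSLSGSHHNWCFTKRQTKISSAEIVAILYLDYNDCQILQPSGTWLGKYILRKLRIQPFIAHGID
IRPMNAEHESLKLIFHVIYVRLAPHNGDLCFFRNRCFSIERRLCLNDTVLADVEVRFTDVRPNSDITTES
RAVSAQDTHVRFKETNVAFLGSCLTFLVELSSFNKISPSLQYAYLITTSFYNAVQAFAMTTQSRSFHEIG
VWCSVFYASYFYMEFKRLEGKLWGAYPEEDLVIKLALVMMNSKKESIQPDVFDRWLHWFYNVVDMGELFN
PKDSVQTL
>Pyridoxal_deC_seed6
GKIHAGFTKVRKTMSKDQLGSSFAVDEIAIRICRCTKIPASSKFYSDQVDYNVSSSPTRYAVCTNRLIWG
VVKQTFYRPRGEPLLLECCLKKVAPSFVSVRIGFAIGYYIKLRNACGLPVKNHKPLLKPGMWSVVATFWG
IQLRAYYSASGVHANWGFTLRHTITSSAAIVGILNLDYHDPVILQFPATLLGTKILRKWRIVPVDAHGID
IKPMDAEHEPLKLIEHVISVGLLSHNGDCAFFRNRQALEEKWHAANDTVLADIAVRVADIRPNSLQTTES
KALSAQDTHVRFKETNVAFLGFHQFILVILSSFRKESPSLQYAYLITTDLYRAVQAFAWASQSKRFHEIG
VKLSVGYASYGYMERKRLEDALWGAYPKEDLVFRLALVMMNSRKEPSQPTVNDKLLHKFSCVVDMGELIN
PIDPDQFL
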