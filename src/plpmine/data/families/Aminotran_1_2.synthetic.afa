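>Aminotran_1_2_seed1
AGIHLLTDEVPRYSSAILLRFSFAVGEFEIDKAVQFTQPARQRFYYEDVDYRVSTSDPNAAVTECFSLDL
NFNQTAGAMRLEMLLLLQCRKKNHNLNESVKKGIADGAYIKLRLALRLDGLNYGPLVKPKGWSKVEEALI
IALKEAWLLYFSHGNRGNSRRVTFTGSSELVGVLHADYFDEKQLRGPGEWEHEGILRKLRICSDDLPGID
PKSMNAEHYSSRLRVLVIYVKGAPNFEIQAFSKNGGASTINEAGGVDIIVLAVAQIVADDCPGSMKTQKS
KAVAEQLGHVGFSEMNTLFLYTRLERVLLLYYNKKESPSLQYNSLGFSSELNSIDLYGLTSQSYGFAESR
GWLSVGTASYCYYYAKFLLELGLKLYMNENLIIKAEWVYAVFYGVINQPTVIDLHANAFSQWNDYEMLEA
PEFSRVMT
>Aminotran_1_2_seed2
GGQHALTTEVVRYTPAILQDTSFAVDETEIDILGFFTQPAVDGFYYADVDYNVSTSDPNAAVTHCTSAAL
NFNQTKGALRQEMLLLLQCRKKNANLEGSVDKGGLIGAYIKLGLALRQGELNWSSQLDPKGWSKVAISLF
IGAKEAFILYNSDGNRGNTWRVTFTSSLELVGVLYLDYFDERNLLGPDHWEATGILRKLRIVSGDLPGID
PKVMDAEHYSLRLRILVIYVKCLPNNEIQHISKKRGALTFNEECLVDTVVQDVAQIVQPNEPGQMETTKS
KAVGEQATHVRGSELPTLFLYTHCTKVQALSSTKKESPSLQYASLIFSSVQNPVDAFGMTSQSSGNAEYG
NWLPVGTASYCNMYERGLQDLAKKISMNENLIFKAAWVMLSYAGVVLQPTVIDKECVAFFNWMDSAFLAA
PEFSDCFT
>Aminotran_1_2_seed3
ARIHALTSNVVIYSPFILWDTSFAVDEFEIQECRFFTAPPVQIIYYEDVDYNVSTSDPVAGVTHCFSLHI
NFNQLWGEHGLEMLLLLQCRKVNHVLVESEDKGFHIGEYIKLRLALKLDEWNWFSWLDPKGRSKVAESLI
IFAKEAWPLYFSIGNKGGTRRVTFTSSLELIGVCMLDYIDFKFCQGPGHQEHTGILRKLRIVSIDTPGVD
PLLMDEEHYSLRARILVIYNKGLPNVERQHFAINRAASTINEEMLIDTVVRDVALINHPTAEWTMRTTKS
KLVDTQDTHIRFSELNTLFLYTRLTRVLALSSLKKESPSLQYESLIFSSIDNPNDAFGMIPQYYGIAESF
NWASIGTASYCYMVAKLLQDCAWKEYMNAALIFKAAWVMAVSYEIVRQPTVIDKAQVLFSSWNDSHMLED
PEFVDCMT
>Aminotran_1_2_seed4
RRFHALTTEPVRISPLILEDTSFAVDEFEIDECRIASQPAVLRFYYEDVDYNQSTSDWNAAVTECFSLHW
NFNLTKGAAGLEPLLLLQCRKKNEVLVETVDKGFCPCAYIKLRLALARGELFWFPLLDPKGHSKVAESLR
FFAKEIWSLYFSDGNHFVTRRVTFGSSLELVGVLYLDYFDEKFLQGPGHLEHTGRLRKLRIVSDDLSGID
PFQMDAEHYSLRLRILVFYVVCLPNNEGQHQSKNGGGSTENEEALVDTVVLDVALIVWDVEPGSMKTTKS
KAIVPHDTHVRFSDLNTLFLYTRPTRVLELSSTKKESPSLQYASLRFSSVENPLDAIGMTSQSYGFAESG
NWLSVGTASYQSMVAKGLQDCALRNYMNEELIEKAAWVMAVSYGLVTQPTVLDKWLVAFPVHNDSEMLAA
PMISDYMT
>Aminotran_1_2_seed5
AWIHLTLTLNVGMSMLDLLDTSFAVDEFEIDECRFFTQPAFRRKYMEDVDYNVSTSDDVAAVTHIISLHE
NNPQTLAAAILEMVLLLQCRKKNAVLVESVVKGTAIGAYRNLRLECKQDALNWISLQDPKGWDKVAESAF
ITAKEAWSLYFSAGDRANTRKVTFGSSLELQGVLYLGYFDEKFLEGPGHWEDSGILRKLRIFSDDLPGQD
PKVMEEEHYSLRLIILIVYVKCLPNNEDRHFSKGGLASTGNDEALVDTVVLDVAQVVHDVAPGSMLTTKS
KAVGAQDTHVRFSILNTLQLPTRLTTVLALSSTKKESPSLLYAILIFSSIRNPVEAFGMTTQSYGIAESG
NWLSVGTVSSLYMYAKGAQDCAWRASMNENLIFKAAWVMAVPMAPKLQPTVIEKWLVNISNWNDSAMLMA
PEFSDVMF
>Aminotran_1_2_seed6
ARIHALQTEVVRYSMAILLDTSFAVDEFEIIACDGFTQPAVQKFYYEDVDYNKSTSDPNAAVTHSFSKWL
NRNQTRTAADCEMLLLLQCRKKNAVLVEEVGKGFLRGAYIKLRLAMRADELFWFSRLLPKGKSKVAESLT
IFAKEAWTLYFSDGNQGNTRRQTFTSSGECVGVTYRDYTDKKLLQDSGHEERTGILRKLIIVSDVLPGID
SRLMGAIHYSLRLRILVIYVKQLPNNEIQHFSKNGGASTVNEDALVDTVVLDVAQIVHDVAPGSMMTFKS
KAVGEQDTAVRFSELNTLILYTRLTRVLEASETKKESPSLQYASLIISSIINNVDAFGMTSQSYGFLDSG
NWLSVGTASYCYMYLKGLQDQAWKAYPNEVLIIKAAWVMAVSAGIVLQPTVVDKLKIHFTNWNDSEMLEA
PEFSGIMT
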