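>KS_seed1
YRKGGAKEDTFNGPYSLLNSRYSDKVRVGVAPQATAIPAVIPKRVKVPSNTRRHEIMAGVFSTRPNDEDQ
DFTGLARLATRNMGNVPSGVDKGPAAMVTSSTIIDPEPVTNKRARGLLMGEPPYKAAAPFRTRGEGNFSA
SVWKVAPSDISQVDALPVKNPEDQICKMRRDFICDSARFVEGCALTYMGPQQSKITESWTGSIGCALSAS
FESSPFGKFRHEYQVNPPLELFSPARVDTVSREIPSPRSHFSSWKGASQLKHDRKETRDKLDSIDRTVNL
QRQRELGIVHHYAADLNGFYGNTGQGNTIFPDVIARTDADKSVSTMKEFVSLEQAKGDYHFPESCIGEDM
HSGGGSGECECAGRWDTMTSHAMNQRPWAYLERFGPGKVRFCDGHFPMLEGGYQLQALFMGEYSCYFYIF
>KS_seed2
MGRGGEKEDTINGPYPLLNLGYSTKVGVGSEQLATEEPCNRPKVSVVPSNTFRSIEMAGVFSTRHVDEAQ
DFTGLARLLFITYANVPPGVDRGPALMVYYSTVDDPEPNFNRRARRWLMGIPPYKAGAPFRTGTEDNFTM
SNWKVAPSIISVTDAAPPKRPADQICKMGRDNNEDTERVTIGLALTPEWPQQYKVTEPRTGSMGCYISAQ
IESSPTGKFRHEYQVAPPLELYSPHRVDTNSTEIPSPNTAWSSWKGYSQLKEKFKEQRDKLDSIDRSVNL
LEQRAYGESHHRAGVTNGQMLNSGQGKTAFPDVIWFEDAQKSVSTVRQFNSDEQADGDYPFPEYCICEDM
ASGGGSFECDCAGRHDGMTPAAVILKLWAYCERFGPGKVKFNDGYTPMLEGGYQFQGCFMFESYLANYRE
>KS_seed3
YCRGGAKEDTIVGPYSLLNLRSSTKVGVGSEDLATLISHNIPKISVVPSNTGRHEIPAGVISTKPNDGDQ
GFTGLGRLATDNYANVPPGMVRGPAAMVYTSTIVDPEPVFNRIARDLLYDFAPYKIGASFKTGDEDNTTF
SVWKVAASEISQTDALPIKIPEDQIGKMRKDNRCRSERYFEGLALTPEWPQQYKVTHPGTGSMGCAESAG
FESSNFRKTRHEYQVASPLELFSPAIVDTFSTEIPSNNSGWSSWKGYSLLKHDRKETKDRLDSIDNTVNT
QEQREYDASAHRARNLNGFMLNTGQGNTAFPGVIHITAAGKSVSTCNVFKSLEQAKGDYPTPEYCIFDLM
HSGGGSGECECLGKLDGMTPGAMVLKPWAYGERFGPFKVRFNQGHTPMLEGGYQLQGLDEGEYYCYFYIE
>KS_seed4
MGRGGARIDTINGPYDVLNLNYSTKVEVGSADLLTAIPANIPGISVVPSNTRRHEIMLAVFSTRPDDEDQ
DCTGLVRLATKNMANVPPGVDRMSEAMVYSSEIDDPLPITDRKARRLLMGIPPYKAFAPFRFGDEANTTF
SVHKVAPSDISQTDALPNKRPEDQICKMRADNRCASERKIEGLLLFPARPQQSKITEPGTGVMGCAESAD
RESSPGIDTRAEVQNLPPLFLFSPARVDTNSTIFPSPGSAWTSRKGYPQLKADIKETKDKLDSIHRTVKL
QEQRGYGISAHIAGNLPLFFLNSFQGNTAFPDVIHRTDADKSVSTVRIFVSLEQAKGDYHFPEYCIGTDM
HSGGASTECECAGRWDGMVPAAMVLKSWAYCERQGPGRVAFNARCTPMLAGGYQLQGQFMGEYYAYFYHA
>KS_seed5
MMYFGAKEDTINGPYPLLNLRYSTKVTVGSEDLATAIPANIPKISVVPSSTRGHEIMNGVFSTKPNQEDQ
DFVRLARLHTLNPHNVTPLVDKGPAIMVETSTVQDPEPVFNRRARGLLMGIPSYKAGAPTKTGDEDNTTI
SVKRVAPSDISQTEALPVKRPEGQICKMRGDNICDSERFFEGLALTPELPQQSKVTEPIFFTMGCHESAW
IASSPGGRTRHEAQVAPPLELPSPARVDTVSLEIPSPNSAWSSWRGYSQLKHDIKETRDKLAVVDKTVNL
QEQREYGISHAKHGNLNGFMLNSGQGNFAFPDVRLITDADKVVSTVTEFVYLEQAKGDYHFPAYCIGEDM
HSGGGSGELECAGVLDGMTPAAPILKPWAYFQRFGPGKVRFNNGHTPMLEGGYQLVGLFMGEYYCYFYVW
>KS_seed6
MGGGFEKEDTIRVPYPALPLKYSTKVFVGSEDLATEIPANEPFISVVPSNTGRHEFMEGVFSTRPNEEDL
TFTGLARLPTITGANVHPGLDRGSAAFVSSSTRDDPEPNFNRRARGLLMGIPPYNAGAPFRTEDEDNTLI
SVWQVAPSLTFQTDALPSKKPEDQIVRMKRDPRCDSERFIVGAALVPALPQQSKVTHPGTGYMGCAESLQ
FESYPIGPTRHEYQNCPPAELFSVERVKTNTTEISVPNSASSSWKGYSQLKADIKETRSDLFSRDRSVNL
LAQGEYGISAHIACNLNTFMLNSGQGNTAFSKVIHFTDEDKSVSTIREFVSLAQAKGDYHFPEYCIGEDM
HSGGGSGECEYATDWDDMTPAAMVLKPWAYLERTGPGKVRCNDGWTPMAEGGSDTQGLFMGEYYGYFYIA
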