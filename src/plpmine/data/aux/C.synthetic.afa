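>C_seed1
GEGATIAANREMTNLKHQNRGLVQAKSIDYHGFEWDLIRPYVLGNTFNATGTFEKTILIGQPDVLGPYGG
LKEGSIFDALDLSLMGIFIAAEAPNTELALAGRNNYRNERNDDFLPFNQGTNVPWREHNTTLDQNKAAAS
NDGVMSLNQFTPIHNYRVVVQLHFMGIGCPVLYKDMDSNFPPHNGSVTLWTALISSQNIYSHRTCGPNRA
LAANRLKSAYKQCRRVKSDDLKARQTLFACDVDVTATVVGCVGQHDTVAGFAKECFTYGVREDRMLCFMH
VAQLGRQRKYNPISLSLNIGETYLFFFKMELMSSITTAPSLSCARQRILTGTFLHEAQFSADKSCSGEGY
VYPGLKIKSYSPQILYTCSLTSERPADTVISCGKAEGPRYAPHGDDSYVDRNVLLIVTDPEDRSDSDASY
VSNRSVHNGIVLPQNFSARIESAVL
>C_seed2
GEGNTFKAVREMSPANAQNEGVVQARSMDYHAFEWRKCIPYVLGNTGNLTGLFDKRILIFQPDRAGPSGG
LKDGSVFQALDLSAMGRIIIACEPNTELAQEGRNNCRQERDNEDWVFNQKTKVPWREENTIADFNYAAAY
NDGVMSWNYFTPAANYGVNVQLHQMGIGLPVLYRDFDSNIPYVRLLVSLRTALISSHNVYSARTLGSPRA
LAADRLKSEYKQCKAVKSDDQKERQTLTCCDVDNTFTVVFCVRQFATVYGRAREQCTYGVIETLMLCFMH
VAQLGRQLWYNPISLDLPFCEVYTFTFTMELMSSITSAPSESQARQRELQGLFLALAEFSIDGSCYGEGY
VYPDLKIKSWSPFIGYTCTATLEKPAQFIISCRKCKGPRYLPARDDSYPDIDWLLFVTINEERSLSDASY
VSNRSKANGRQTNLWKEYRIENDVL
>C_seed3
GEAYTFKANKGMSSANLQNGGLVQAKSMDYPGGAWRLVIPYVLGDTCNETGSFDKTELIGQPDRKNPYKG
AKEGSVFEALDCSAMGKFIVAQAPNTECYLEGRNNCRQARNDEFWAFNLETKNPLRDINTELDFNYALAS
NDGDMSLRYFTPFANYGVNSQLHGMGIGAPVLYKDMDSNFPMARGLVSLGTALISSWNVSSHRQLGPVRA
LAADRLKSEYKQCKRVRSDDLKEKQTLFFCDVDNAKTVIGLVGQFATVAGIGKEQTSYGNIEVNMLCFMT
VAQLGRQLKYPPISLSASFCEIYTFEFTMELMSVISSAPSESCARQRELFMTFLHAYQFSVDGSCSGTGY
VYPDLKIKSWSPFILYTHSLTSEKPADVVISCRDAHIPRYLPPRDDSYPDGDNLLIVLINEERSLSDLSY
VSNRSRANGIIKPLNKEYIIENEVL
>C_seed4
GEGARFKANREMSPANALNRGLVQAKSMDYHRFEKRLIPPYVLGDFGPATGTFDKTILEGQPDRLGPYGG
QREGSVFDALLLSAMGRFITACAPNTEQELHRRNNCIQERNSEFWNFNQETKQPWREEHTSLDTNYAAAV
NDGVMSLNYFTPIANYGVVVLLHAMGIGLPNLYKDMESNFPMHRGLVSLGTALISSWNVYSHGTLGPNRA
LALDREKSEQKCGLRLKSDDGKSKQTCFCPDHDNTLTVNGWSGFFATVEGIGKDQTQPGLKEVRWLCFMH
VFQLGGQLKYNPEPLSLNFCEVDLFTTTMELMSSITSAPSESCARQRPLTGTGLHATQFSVDRSRHGEGY
VYPDLKRKPWSPGELYTPSATSEKPYDTVISCRLADGPNSLPHIDDSYPDRRNLLISTINEDRSLSDASY
VSDRLIACGIISDLNREYRSHNEFL
>C_seed5
GEGATMRANREFSPYNEQIRALVQALSMDYHGFEWRLIIPYVLGPTGNLTRTFDKWSLIGLPDICAFYGG
LKEGSVFDALDLSGMARFIIACAPNTECHLAGINNCRLERNDEFWNFNQETKVPWREEATELDFPYHAAT
KDGNMSLNYGTPIANYMNNAQLHDMGNGLPVLYKIMDSNFPMHRGLVSYGTAWISSWNVYSHITAGPNKE
LAAQRLFSEYKQVKRVASDDLRDKQTAFCCDNGNKLTVVGCVGQFATVGGIGKIQATYFVREVRMLCFMH
VAFLGKQLKYNPNSLSLNFCEVYIFTFTMELMSSITSGPSTSTARQRALTGTFLHAAQKSVGRSCTGEGY
VYPDLKIKSWSAQFLYTCSATSEKPLDTVRSCRKGEGPRYAPHGDDSYPDFHNLLINTEKEDRTLSDLSY
VSNRSIANGIIEPLNNEYRIENENL
>C_seed6
GEGALTKENRIMSPADACNRGLVQAKSMDYAGFEQRLEEPYVLGVTCNATTTDDKGILRFQPDRLGPYGG
LKEGSLFDAADLSAMGRFIFACAPNTECALAGRNNGDLEGNDAFWNFNQETKVPQREENTELDFNYLAAS
NDGCMSLNYFTPIANYLVGVSLHIMGRGLPVLYVDMESNCPMHRGLPSKGTALISSHNVYSCRTLGINRA
AHEHRLKSEYKLCKRCKSDDLREKQTWFPCDVDNTATVIGCTGQFATVAGIGKEQFTYGVREVRMGCDGH
FAQCGRQLRYNPISLYLVECEVYTFTFTMELMSSTTGAPSESCERLRESEGTFLHALYTSVDRSCYGEGS
VYPDLKIKSWSPQTLYTCSATSEVPRGTVISCRKAALPRYLPHRRDSYPDRENLTIVTEVEDKVLYDASY
VSNRFIANGIITPLQKEYRIENELL
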