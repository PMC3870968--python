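>TE_seed1
LDELAGGLLGKGYITVEHLSQQIGDDCPGVMIGDNRTPMDLLQNVASEQLVNQDPPGSEHNSHTPTESDD
PICSGCTLLKDCAQMTPPRFASNVGPQILGADGEGHCQRTIGYSKAFLGMSGTRPEINHDIACYLQIYKM
ALPSLTIEKTPNRPGPSNMIPTSHHLEAIMEAMKRDPMPAGSLDDAHTAGEDKPTPSEQHYASDLDPRMG
PQLYCKYGVPNKPNITYSGLVSVGAIYNAI
>TE_seed2
LIELAGGLLDRGIILVEHLSWRECNDPYGVMVGDHKTPMVLLQNIALEQLVNQDMPDSEPVEHTNDESDA
PKCSSCALNKDTAQMTSSKFASPVRPDRACADGDRHCQRTVPYSRAILGMSGDRPEGNHDIAQALRIYLM
LLISLTVETTPNGPGPSNMFPTSHALHDKMETGKIRPMYAGSLSDAYRSGEDKPTPTEQHYATLLDPRMF
PQLYAKYGVPFKPNFTYSGLVSLGDIYKAF
>TE_seed3
LDEAAGGLLGKGEILNEHRSQQICDMSYGVPVGDNGTPMVALVNIALEQLVVQDPPDSEPNSHSPTESDQ
PEFSVLALKKDTARMTSPRFASNVGPEILGLDGLRHPLRSVPYFKADLGMSGSRPDGNHDIRCALQIDLM
ALPSLFVEKFPNGPGLSRMLPTSAELEEGMEFMKIDPMWAGSLPIAQTAGEDAPTPSENAAASLLDPKMD
PQRYGKGGVPFKPNITYSGLVSLGAIYNAF
>TE_seed4
LDELARGLLGKGEISVEHLSQEPSDDPYGVMVGDNFTPMVLCQNIALECLVNQDPPESENNSHTPTESDD
PICESLALLLDTAQMTSPGGQSNVGNEILKADGERWCQRTVPSSLADLGMSGSAPIGNHDIKVALQIYLY
ALPSLTVIKTPNRPGPSNMFPTSHALEDRMETMKFDPMYAFSLPDAYTAGEDKPTPSEQHYASLVDPRMN
PQTYGKYGNPNKPNITYSGLISLGAFYNAC
>TE_seed5
LDHLAGGLLRNGEILVEHLSLQFCDDPYGAMVGDPRTPMVLLLNIALEQLVNQDPPDSEPNSHTPTESQG
PICSSCPLLKDTACDTSPRFASAVDPEILGADFKKQGQRTVPYTAAIAGMTKSRPEGNHDICCALGIYAM
ALPSATVGETPNGPAPTNMFPTSHAAIVRMESMKIDPMYACSLAEAYQAGEDDPTPSRQHYASLLDPVMF
PQAYGIYGNPFKPNITYSGENSLGARYNEC
>TE_seed6
LDELAFGLLGKGEILVEHASQQECDDPYGVMVGQARTPMVLLQNIALEQLVNQDPPSSEPFSHTPTESDD
PICESCALARDTAEVTSARFASVNGPEILGADGARHCLRTVPYSKAIAGMSGPRPEFNADIACAGQIYLM
ALSSLTVEKTPNGPGPSNMNPTTHAQEDRMGTMKIDPMYAGSQPDTKAADEDRPTPSEQHEATLLDPRMG
PQLYFKYGVPFKPNITYSGLVSLGYIYNEY
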