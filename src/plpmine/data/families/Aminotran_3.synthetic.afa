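>Aminotran_3_seed1
HKIHIKTTEVPIYVPGRGLDSSFAVDEIEIDNLGGTTAPAKLRFMYGDVDYNVSSSDPGYAELPNRTLAL
VFGKSTYFPQFEFCLLAQCMKKNCVQQEFSKRGVEIGAYIKAKAALGLDQLKQIPAGDPKGWSVNAMSWK
IDAKAYMTLYQSHGLLKNTQRVTFSRYLEIVGVLYLDAMDQVIGQEPDHWLGTGVLRKCRIVSDVAKDVD
PKNMDLEHYSLKLEICYFQDKSLSVNGQNHEPVNKGRENGNAELLNDTVIALVAVVVWSLASGHMRSTKS
GCFSNQDVHVRFSECNNATKGTKASGLYHLEYIEKESPSLQYLSLVTTSIYIPNILTGPTSISRAGHESG
VWLSNGTNSSCYMVAKGNIDAALWAYMIVVLVIKLAWVMHASKRPPTWPTICEKIAVKFSNLAKYIGKVN
PARSRQMT
>Aminotran_3_seed2
HEEHEKTAEVFFYSPGKLADSSFAVDEIEIDNLLRTTAPARLRIMQGDVDYNVSTSDPGYEVLPNITLHL
VGKLSTAAPITEMCLLAQCMKRNLVKQEFNRVGKEVGAYIKLKAALRLRQLNQVPLLQPKGWSVNAESWF
RQAKLQPTLYMSHGLCKNTLPVTFSSSLEIVGVLYLDAMDQVTGQEPDFWLGTGELRKCRIVSDDGRDVD
PNNMDAEHYSLKLIICSFQDQYLSKVLQNHEPIRDRGDNGVAILLNDTVIADVAVVVRSLHSGKMITTKY
KATSNQDVDVRFSEGPNAERLTKLSIAQHLIPIEKESPSLQSLSLITSIIYNPIILDGMTSISRAGIESG
VWLSNGTNSSCYMVTKFLFDAERWAYPICVLVFKLAHVMAASAKPPDQPTILDKILVKISNANTVIMRVV
PALSKQMT
>Aminotran_3_seed3
HRIHDGGTEVTIYSPGNLLDSSFAVDEIEIDVLRETTGPAKLKFMYGDVDYNVSTSDPGYEVTPNVFLHL
RGRLGTYAPRFEMCLLAQCMRKRLVLLEGVRVGREIGAYIKLKAALRLDVLNEEPLLRPKGWSVNAESWM
IQARAYPTLYFSHGLARNTLRVTFSTSLEIVGVLSLDAMQQVFGQEPDAHLGGGHLRKCRIVSDDERGVD
PKKMDHEHYSLKLRFCKFQDKSLSNNCQAHEPVNKGGAVALAELLNDTVIADVAVVVWSQESAKMRSTKY
KALSNQDVQVNTSEANNATRGTKLSILQHWEYDEKESPSAQYLSLITSSIYNPVELTLMTSISRGGWASG
VWLSNGTNSSCYMNAKGSVDAGWKAYPIIVLVFKLAHVMHLTCKPPDLNTICEKIELTFSVANTSRMRKN
PFFSRFMT
>Aminotran_3_seed4
ARIAEKTTEVSISSPGWLLDSSFAVDEIEIDNLRRTSAPAFLVFMYGDVDSNVSTSDPGYEVLNNIDLLQ
VGRLVFYLPRFEMCLLAQCMKLVLVLQEFVRIGREIGLYVKLKAALRLDLLNVEPQLDPKGWSVNAESWN
IQAKPYPGLYMSHGLAKNTLIVTVSSSLEIVGVLYLDAMDQVTGQEPKHWLFTGLLRRCRIVSDDEKDVD
PKNLDEEHYSLKLRICSKQDKSDSNNAQVEEPVNKGREGGNAALLNDTVIADVAVVVLSLHSGKERSTKY
RASINQVVHVKFSEGNNATRGTRLVILQPLESIEKESPSLQSLSLEGSSIYNPSILTGMYSISKADWESG
VWLSNGVNSSCSMVAKGLIDAEMFDYPIRILVFKLAHVMHASIKPPDKPTVCEMILVKFSVANKTVIRNN
PALSRQMT
>Aminotran_3_seed5
HRIHFKTTEVTITTPGKLLDSSFAVDEIEIDNLRGTTAFAKLRDMMGDVDYNISTSDMGSEVLPNTTLHK
VGRLTLYHPKGSMCLLAQCMKKNLVLLEAVRIGREVAAYVKLKAADRLDQLPGEPLLDPKGWSVNAEPWF
IQGKAYPTAYFSAGLVKNTDDVFMSSSLEIVGVLYLDAMDQVTCQEPGHWLGTGALRKCRIVSDDAKDVD
PKNMDAEHYSLKLIICSTQDKSLSMNAQVAEPIPFGRENGKYELLNDTVIPDVAVTVWSAHSGKPSSTKD
KATSVQDVVVRFSEGNNFTRGTKLSVLQHLESIEKESPSLQYASLITTFIYNPSILTGMTSITDLGWESA
VWLSSGTNSSCYMIAKGLIVAAEWAYPVNVLVFKLAHVMPHSVKPMDLPFINDKILNKISNLSKSFMRFK
PLESVQMT
>Aminotran_3_seed6
HRVHETTTEKTIYSPGRLLASSFCVDEIEIDNLIGTTAMAKLRFMYGGVDYNVSTSDPGYENLPNRTLHL
VGRQTDYLPRIEMCLLAQCMKKMLVLQEFIREGREIGAYIRLKAGLRLAQLNQVPLLGPKGHVVNAESWF
IQAKYYNSCYFSHGLLNNKQRVSFPSSLEIVGVLYLDAMDQVTGQDPDHWLGTGSFRKCRIVSDDAKDVD
PNNMDAEHASLKLIFCSFQDLSLYNNGQVHEPVNTDRIFGNAELLKDTVIADVAVNVWSLHSGNMRSTKA
EATTNQDVHVRFSERNLATKGTESSILQELESVDKESPSTQYQSLKSSEIYNPVILTGMLPISRLGWEPF
VWLSNGTNSSCYMIEKGLIDLAQWAYPFIILVFKLAAVMHAPNKPPDLPTICDVELIKFSFLNKSIMRNN
PAASRQMT
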