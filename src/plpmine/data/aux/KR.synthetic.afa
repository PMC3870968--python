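>KR_seed1
LPNREMTIGPVVTYQMRHKLEFNVEDGNTETNGLYNGGIARETITLVLDWRELTNEHNGDDSNGDTVQCT
GEKISNGFKAATRHRADPEGGFYYKVVVGGGSRVFCFAMLPTPGDDSGKSFHLQPHFYGDEITRALGRVN
IGVRLNDSHREHDVHQPNVECVADPVCNESSNNVFNFRMT
>KR_seed2
LPNGGWTRRPIFWYGMGHKLASSVEDGNLLTTGQYQGGGARRTITGVLDHKELTSNHVGDDSNMDYVLCT
GSKFSNGFKHLTRARGEPAGRFYYKVVVGGGSRVFCTAMLPTPMDDTGDSFEGQDHFYGDEITKALATYN
IVVRLVDSHREKDVHQDNVEQVHDPVNNASSNKVFNMIMT
>KR_seed3
QPNGIMTKKPENVYQARHKLESNVEDCNTETSGQYQGRKARETITRVLDWRELTPPHFGDDTNGDYVQAT
LEVISNGVKALTRHRGDVHGFTYYKVVIGFGSRVFVTNMLPTPMDDSGKSFHRFPHFYGQEVTRALAFVN
IVNKLLDSHREWDVHDPNVEQVHDPVCNLSSNKIENFKMT
>KR_seed4
LPNGIMTRGPIRHFQMGAKLESNKEDGNTETSGQYQGGHAAETITCVLDWRELVVPHNDRDSNGEYLQLL
GAKISNGFKALTRHRGGPAGGGYYKVVNEGQSKNLLTAMLPTPMDESGKSFHGQPHFMRDEVQRALATVN
IVVRLVDYAREHDCHQPNVEQVHDPVCEAMSNKTFNIESI
>KR_seed5
LPNGGMTDRPINHYFMRHKLESNVEDGNTETYGQYQGGTARETRTGVLDWLILTPPWNGDDSNGDYVQCT
GAKISNGFKALTKARGDPHIDFCYKQVVCGGVRNTCTAMLPTPMVDSGKSFHGAPHFYGIENTRALAGVN
VVQRLVDSHRAWDVHQPNVEQVADPVCNESPNKVTNIRMT
>KR_seed6
LPVAIMRRKPVNHQCMKHFLESNVEDGVTETSRQYQGGTDIETIVDVLDWRELFPPHNGDKSNGDYVQCF
RERISNGFKDLTRHKGDPHGGFYSKVVVGGGSGVFCTAMLPTPMDDSGRSIHLQPHNYGDHVTRALATVN
IVVVLVDSHRERSVAVSNIAQVHDMVCNASSNKVFNFRMT
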