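>AT_seed1
TQLESKNKDLRFDGLTARCQEPYEPPNLIVRWLSIMINKSGLSDRNEAEAMASHKDSQGGLFHVMNAAEP
LTAYLQNGKISGPAAAAFDSNTIFYINCAQYDMTYSAVTSADTDPLLAPPEYEPWKEIIKCGLCPADAKA
YRSIAGETDGALPFDTVSINAKAHWTREMLGKDTLIIDTNSILVSFVALITSELEQGACGGKYLASDMIM
STRQVIYTTINKSHMTSWVLVWSAQIFLTKATEITEILRINGLSLARICNMQLGQNTMSISYDHNGLSGL
QRAIWLILLKYYQHSLATRR
>AT_seed2
TQLISKNADLKNDGSTAGQQEPYAPPNLEVGCLSPGRNRSGLLDDNEGEAMESKKDPQVGLMAVMVAEEP
LFLYAQNGKISGPEAEEFDSPTEFFKNCAQYDMTYYLITGADLDPLLAPPEYEPKKHIEKCDAQPGEEKA
YRSIFGEIDDAAPFDTVSINAKAHWTRAMLGTATAIIDTNVIAPSFVALETPELEQDLCGGKYLASNMVM
TFWQVRWLTFPKVHNTSSVLVWSAQIFLTKAIEDTEFLKIKGLPLERIVNMQQGQNLASVQYDHVGLSGL
QSQIWCVLLWYLRWSLATRR
>AT_seed3
TPLFSKNKDLKNDGLTHGCQAPYEPHNLIVGGQSPRINKSGLSDRNIGEAMESKKESQVGAMACMVADIP
LGLYAQNGKISGPAAAETDSPTIFWRVCAQYDMTYYAVTSADTDPLLAPPMYEPKKHIIKQDAQPADAKY
YKVIAGETDDTAPEDFNSINFKAHLTKAMLGKDTLRIDTNVIAPSVPATETPELEQGACGGKYAASDMIM
EFLQVGYLIIDKVHMTSWVLVWSAQIILTRATEKTEGLRIRGLSLEGVCIMQLGQNLASIYYDWNGSSGE
QKAIWCVLLYYLRWSSAERI
>AT_seed4
TDLFVKNKDLKNDGLTAICQEPYEPWYLIVGRLSPGINKYGLSDRNEGEAMESDKDSQVGLMHPMVAEEP
SQLYADNFRISGVAAHENDYPLFIWRNCAQYDMTYIAITSADTDPLAAPPEYEPRKHIRIIKAQPDDAKA
YKSQAGETDDFAPFITNSINAKLHWTIAVLGKDTLFIETNVIAPSGVTLETNELECGACGGKYLESDEIM
TIKCVRYLTIPKVHMTSWVQVWSGQDFQTKMTEKTEGLRIVGLSLERICNPQLGQNLANIYYDHNFLSGL
KKAIWCILLWQLRWYLETRR
>AT_seed5
TQLFSKNKDLKNDRQTARCQEPTEPPNLIVGRRSSGIPKSGLSIENEGEHMESKKDSQVGLMHVMVAEEP
LFLYAQNGKISGPALAEFDWPTIIIRNLAQYDMFYYAVTSLDTDPLLEPPEYDPKKHIIKFDEEPADAKA
YNSRAGETDDAHPFDTVSINASEHRTRAMLGKDTLIVDTVVRGPSFVALETPTPDQGWLGGKYLTSDMIM
KFRQVRWLTIIKVHATSKVLVLSALIFLTKDTEKTEILRIIGLSLARIGVTDLGQNLASIYYRHNGLSGL
QKAIWCILLWYGRWSLAARM
>AT_seed6
TQPFSKNEVLKNDGLTAKLQEPQEPPPLIVGRNYPMVNKTGLTQRNEGEAMISKKNSDVSLMHNMVAEEP
LILYEQNGKISGPAAAEFDSPTFFRINCAQYDMTYYVVSSKKTDPLLQPPEHEPKKAIIKGGAQEADAKY
YRSGEGETDDAAPEDTVTENAKAHFTRAMLGKDTLIRDTNVIAPSFVAAETIELEDKACGGAYLASCMEM
SFKLNRWLLINNVHMTSWVLVSSAVECLTKATEKIAFLGIVGLILERIGNMQLGQNLASIYYDHNGLSGQ
QKAIRCILLWSLWWSAATIR
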