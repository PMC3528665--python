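>seed_cdc6_00 synthetic stand-in Orc/Cdc6 initiator seed (Walker-A bearing)
MGDGWLVYLNGVCNWPLCRIANYPKRSSKHIAGAHITAKLNYVTPFQQYFGWPIGRNEYF
VMGFHKLDMGEEKFGKTSYGFIEHTWCQVINPLYYIGQHHSLYMIVFALWEYVIAVQIYC
HSAFRNAECEEYNIYPVMDLCPFMCPICRYHRIKLRWFAERAQWIWAYIQRINGFHNIVS
MMEANLEGCDIESGYEVVLMGMTLFVGAMRANIHSRRIGVPFTKYGAPWNGCLETEMGKI
IELMTSPVCKGYCEHIVHVASAQPDYGESCNRWPPWPVGSNIGKEFIGQRIKFLKMIASD
NCNPTLWRYANFCDLYWTSEEMQCTLMKDWKSFYKCHDTRPKEKAQLPGPYYRYEMTKRN
PVAFHHWKVIGIKISVIQKMFPDFMLRVMTAWWHNCFWIHPQNRPFSPDMYPQLCSLNCL
>seed_cdc6_01 synthetic stand-in Orc/Cdc6 initiator seed (Walker-A bearing)
MKTRCLQNPLKYAYAYVCGCMVSPSHQTYKRGPGWDLVWWSGELCFGKTMKTYFEASFKG
CCLDCKCNQCSAKLNPICERNYECCFAMLSHWGQSKMGLRPCQHPYWNWDNMEWRILWQK
CCQLSLMYIIFYFAGQQNFPYHDRCFGAHFLIKGIMIMPGRNCLIREHGGANRMRDKMCS
LEPYYKLTHGQPFQVNFCTMRWIRKYERIDFWQNETCWNDWITWFTIGWFHHDQLIAHVH
VPLKETPTWETWLQLCDDQKWCTLYNNGQWCAWRVPLIETSMEHTLKQWQKQRWFGYSIS
MPKHFSTYVEFLYDWNGGVIAPGPAKKPCIHWCCWLSVGFLIKALNPFMAEVPNPWRWDN
KKQLLQHQVGRLPIMMDQSRYGPSWLAHFCAVPCIWGGMHPRIDWQFEHWLWGGPCVFDS
>seed_cdc6_02 synthetic stand-in Orc/Cdc6 initiator seed (Walker-A bearing)
MDQTKEGASTTCLDRDYTDNGLYWYKSGKQAHWQFFVEVAWSITEKSVEFTVWCGFRRAG
KTRMNVGIAETDEFKQLWQYHQGECAPAKYWWMKHRWQWPEHSEQTIEWYNEHLMTYSWC
CHYAMMIQMMRQWLEIDWDDNEFFWVLMKCHQLRPYTSTLRDMNLEHDFCSFIFRFRKYM
ELWGPPAKAHFQDIDFGWVWYSNACDPGPGFMLRPTETVEVHMAWRKGLDSIPFSKCDPS
VVGLPNWNIFACVMVMVVHCMAIPMRVGMANLAQRCDCGQHMAFIKMVWHGPMKRPQEEV
YVYIYEKCDWWTGRRTTINKGDMIKILKRFDPWYRHHLRTACFKLLWSTDVGNICMPKYH
YTQEEYKMCFWIPMIGFSKAMQIDFVWPHGHYHRRYNWHAKLQDHMIDKPFRRTQSTLDS
>seed_cdc6_03 synthetic stand-in Orc/Cdc6 initiator seed (Walker-A bearing)
MTRGNHRWMISAYTYKQGVQGGMKNDYFLGSTWQNKPRHFRRPQEHWQHYSIIVRCQEWY
KGRFWHGKTEKVCACCPLQTSSCKIHKSTFDIQYKLPYDRFNLDTCEWKQTMHAALMYEA
HYNMTLHMRSKFNHSKHKRTNCRNYANAFRQWAPWQTHCWAQQCQVFHDDYVSMRWIQPS
DVLERPDQPVQNEKRGPQNQFCTQGSSYFIINWYKIAIVRWLWGNILLWQRGAHPIRRDY
AHRTAEINYAINRLQPKFRNWNVRCNNPFYAVGHHTFSSSMVRFKFLCYKPDCEKEPLDP
QQPICFEISTVWDIFCYNVWHDRACVLGEQHLVRMCPLMPLDICQVIKMETVKDFFFPYE
QFSAERWHSDCDVFFKWTIIITISWSDENVLDEWDLRQAPYLARRAPLSKYKKVLYWQCT
>seed_cdc6_04 synthetic stand-in Orc/Cdc6 initiator seed (Walker-A bearing)
MDWHEFNFRAGHYRVAFEHWRDSGDACKHINWEGYGPKDRHGQNYLGKTGYGILPRFKNL
MADVVATCVIYSLNQINLRTMMDHFVILIVLASTLKWKWSKFSQNRYCCSVDMHPCWCVN
TRTTYYDNNTKPTLMEHGFLQRAGHMIVTTMMKYLKGQMWPKGWIYAWRHMPIIKYIQLW
DEPHKHMSCQSYYQHNPGFPVSHTVRQRFKFGTHIDPKYWWIQLSCTRRCKDWCDPMIDW
GFMKMMVNVCHEEKVTMAYIYLDLYRHATCFEERMNMQYTRYESWKVPRCVDWSDDKIRD
VWIGAMEWHVVSQKQCWVYFKAWVGCTDQGSPPFGWLAQMWMNYRDAEMWFGFLTQYHTY
ALHGECYWMEMNETMAVGNTHSFTPVQKKYCELYSWWKLGHMSKVELEFVAWHEFGTESF
>seed_cdc6_05 synthetic stand-in Orc/Cdc6 initiator seed (Walker-A bearing)
MEYPYFMTRWPGHNNEKKIFWDCYIYMSHITGLDFYPWNNCNNDRGTNAHGKTRWMLDTL
VHVQPWNKSCLIENDNLYDIDIQLLHHIHQKYYVSTRMSTHMFMKHGIWYISYIHCVQGI
LYERCARSCRQPNGCNNELAHDTRCMCVITARCWHIPKKFGTLQPGLKKVQTKQDSFMGI
INCPCGMIAMKGCYVFFSLKHCPRMDIIQHQQLERYNNMTRPRLWVESYMYKPKQGWKMT
KRTVQLWNGHPCPDQWFMEDLYVVGNKSPEPSCPVHLHAKGWNCRHGFRSYRCFCIMRYE
PYMKLRLVVTHHLSFPKEAVCETTLADGGVNDKNHTPCRDHLGEGLTPNKKYIIGLLCRE
RCKKSHLCMYWHVPCFIHKAKPNEQYIPSIAVACHCDYLMIELWTCGSFIPLWDPWKKIQ
>seed_cdc6_06 synthetic stand-in Orc/Cdc6 initiator seed (Walker-A bearing)
MGFKRMIQWCVNSIFRQFWLMMYLKNIFFNCCCSWISQKGSQQNGKCICDFLMNKHGVAK
DHECTELATKWFQCHLLRPGMGGTGKTQCLPYAWVLCVQAFEVTVIFSWHVKNNYQGRDA
QNNFPQCVYHIILPCRPWPERAKMFVMFRVSHPGCTNTIRQNISTPENYAVYGYLWFNTE
LLPTGQCVDCSMDSVDWRWFWMAMDPPVHKRKNPIGRMSYPDISKAIGAFEWMPRAKRMV
IWSNYMVGYHMNPRKYKCWRWSFFQCWFTQTACAALLLMRGNPRSTHPQHRRTKAMWAMN
DLSVEAFVLSEIIFYVEECVSQVNNTFESSSSLQTNCLSKEMEWNAAVLLNWHAWFFPVC
ICMGNENFFEMKTGTKGGGLWWIMHKRTSPNMQVGMEMWNKRDNIGGPWVARLPCRSAQS
>seed_cdc6_07 synthetic stand-in Orc/Cdc6 initiator seed (Walker-A bearing)
MLVDLHIFFWKEGWYHKCSNCPRDYSPKDCMWARPSVPGVGKWNRGMKCRNFTIPVPLEF
HGLQFFGKTPVMVHAAIQKHAECVMFKWGMFLGWGSSAVDQNCSRNICIRKMATMTQYDD
ADKEMPHLCMEGDARKDTITWEASSDHECHCRIGDHIERRNIKSYQTEVQWAFNHWEVIK
MAMGDEMIHGKPHKQIDFMMQDPMWYAVVQLCAWEFPFMYCFDERGWTLIRSGWQMICDR
FIYKSWLGYGERIHYVHCPREPSPFSISDRWANDDQPEWLQWQQTFENVEYPCWWCASRL
LDYYTQEPCKDYHWLWQRLNIPPGPDKAFEHFHEWMHPGVSLWSLQSFKELKKVEQQRTG
CTSMMMPTEQIYTRGARMKWFFSWGWIVHAEHLVKQFFHKPCYIDNTLDWVAKEWTIQDD
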