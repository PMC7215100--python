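>CYTB_PNEUCA
ASRHMCANAYHWNWVWMQLEDKDNGSGAWTITMCWTTTLTEQNKVDMLQLVLWGYSSSMW
FLQDTSDCHPWDFCLCTCQDLPEMSGFQGCRSSAPHFRMIVRYYLFNKKIPETPGTNCYH
WLWVCGEYLFQDRIYCIGCQKWHWMEHQHQYQNRENGRTH
>CYTB_TOXGO
ASIRMHMNTAHWGWVWMQLEGKDNYSSADQITGCWTITLTEYNKYDMVQCVSWGYVSSMP
FLQDTMDCHEWDFNLCICQDLPSASGFQGCRSSAPWVRMIVRYYLQNKMIPEWTGTNCYM
WLWKCPRTLFQDRTYCIGCKKWHWMVVQHEYQNAENGYTH
>DHPS_MYCLE
ISEMVSLASFYQRFICWMSVESEHFYGWSIKHKSNHQYEMPNEELPMELCWRPYQAWQWP
ERTMAWPNKDPLIWHWRWIRYGGQVDDAPLAAEKSGQGVIKGDVHVSRCCTITHCGYQPN
IRHGERWLTGYQMRWSCQMTGIEMRSENESCDVGRGKKDR
>DHPS_TOXGO
ISVHVSLAKFYQREIPWRSQESEHFYGWSSKHKSIHQYEMPNEELVMELCKRMNHAWMVP
EISMYWPNEDNLISHWRIIRYGGQVSDASLAADKSGFGVIKHDFHMPRPCHPTMRGYQPN
IRHGERKLVGTQMRWPCGMTGIEMRSKNESVYVGHGIKCQ
>ODC_TRYBR
QLYVTFSNSKVLLIRNHEGAFHSARAQWYHCVFAMSHDCVMIWFTRYILTPTAPFDKTSG
WLSINPDDHFVSCQRRFRGNWYAAMDECLIALVCEREPTYERQRMRDWVGLQATSSTKLP
MTNAKRGPFATTMIPGVETLGGFPYAIKTGKWMTWTVGDG
>ODC_PNEUCA
QIYVTFSNSYVLLIRNHEGHCHSARAQWIAMMCEKSHDCVMIKFERYILTPVPPFDKTSG
WLSCNPDVHFSSFQRRFRGNGYAKMDTCLIALRCERPPTYERQRMRDGVGLTACSFTKLP
PTFAKRGPVFTTMNPGVETLYQMSYRIKTGDWMTWTVGAG
>CYP450_CANAL
DGTRPRPAKPDSHEHWYMAVWYQRVSLPHIGSTGRMVYILQVELIKWYPEVHTEMARRKR
CDHADLQAYCADYKILMGYWFVLASHDDIEMDWAPLIWNCWHTNWNTNQVEQCTISIGSW
TYLMHYLAIFAENGWSSWGAHYDSFPSRWEQVGVVLHRPD
>CYP450_HUMAN
SGTNPRQWMPGSHEHWYSAVWYQRVSLPPIGCTCRHVTILQVILDHSYPNVHTNMTQRFH
FDNADLQAYIAWYDILMGYHFVLASHDAIEMDWAPLIGNCWHTYYRFNQVRQCTISIGSW
EQLMHYKAIEATSAWYSWGCHRHSRPSSPEQVGVVLCCPE
>DHFR_PNEUCA
KPQDQHSKYLWYLIRENFKRCSHRKNCIRYYWKILFNDIDQILVWWMKFAWSKLFGLNKP
FMNKFFCDSSFCINEVSMTCGESYYNMWARALICTNMMFYSHEPWWLIRLDPTRECSMLV
YAEHGPYEPWGMVHCMTQEINLMGRHLNKWINQWTLYCYR
>DHFR_HUMAN
KAQDQHSKYLWYLARSNFKRCSHRKVHIRYYQKILFEDIDQILVWWMKQAWSKLFGLNKP
AMNKFFNDSCFCINEDSMTCGESYYNMWARALICTNMMFYSHIPWWIIRLDHTCECSMLV
YACLGMYEDTPMVHCMTKEINLMGHHLNKWINQWTLYANR
>XDH_HUMAN
FDTIWAIMAEPFLHTFACTYWSHGMKMTPWKGENLMKEHNCPIPDHRKMQMHSEHGSVMP
IMDAIQEVHHYDECDYRTMPVGTVDEGQVRCMPFRMAPLGRYRKDTAMVACCNFTYEKLP
FTLFYLFHKMIGVWYFGLNANTGLCANLALFVADVETWQTPHIHRKTDHLALCICSWVPE
IPMLHACLDILDGLGMYSQKTPVGKRDMSVEVYGLVWDPH
>HPRT_TRYCR
CGGGWRPFHRVDPLDHNWEITSDLAGPTFNFAKMSMWPKSVASEKLQFCMHHNIAWHYVM
MSNVPFNQKICVPESCWYNDTCLSELFVVCCSAPRLDATADPHQGPVAESLNQWTPHHAP
KTFLKMIKLSPAPTNPMGHFIPSQYSCTKDFIAITHPHFQKIYHCWTMRITVSYSKIDSY
EHPRVSSAVGIGQPMYCIHNDMSELVDEFDRFLVAWSHWR
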