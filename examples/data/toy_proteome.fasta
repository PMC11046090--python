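>PROT0001
VSFGTASSLGGGKLMYSPYFEPAALLVPLLFAEQEIASEGTLTPRDLLTINAIHESIYNP
PQEKFKDWFQGTQDTVVNEEVMETPNIKFATLMHRAIADWPKLTHNQILSVEVARSDKSA
PSLRFEIEIVNHGVKYLLVRNKTKVAKLVGSQRPYHKEAFVTDNLNPGWLPPEAKSSRDV
STLVAAAGFENANEQAGVLSPPENASWTAHGDPSGTSDSTENPPDQPSSHRTTEAPFMVI
GLPDIDQSIILFFHLCRNGCSDDDCVGGSPEKTIRDRSSQIALREGLRVDESPRYVTSKP
ERRRKIKATLIMRISVIDSYERSVDDYDENKREVFSALAGGRLAYTVFKFDALDETLEQG
LGLPLKSTEDDYVFWELLVAGNAFLTS
>PROT0002
SSRTQRGEREVNHVELDWNSGSQPVKKQSHQEMSARAVLKRLRCMMVALPMCNFETELRR
MSLPSQPKMKRILRLHSITSKRAITNMQQNKEGGKYIKINVTIGTLQCTGLEKSSLSLIM
EGRSARSKAQFPIPGLLPEWGGGAKSREDHSLVPPSRHGKLEKPDDEGWAEELALEGSEP
KKSEVTQAQNSFVTDGASVYPQQNVPHLARQKTRHCDEGKVGVQTKASFESQFGVGQDSD
LAMTCGSPGPLTGRPRIRQIAWRERGLTKGGCFGEALFRVGNLCDTLSANTTALISCGSL
LWGAKE
>PROT0003
NVNPHNRNSMENLEPSDLRKGILQMDSVDFETVAHELVCELLRKEIYRDSGSATELQLED
GAFDLINGAHRGKRKTVGRGDKNVERLDYQDVDDHVAVPANLMRQYESKSTYGLVVIVKI
RLKIKDARMQSFFGGSIHPEDQRGPAKNGIPNERCWEGEYGPYVALNQHHAAMCEHCAVK
ERAFWVPDGAFADP
>PROT0004
DEVHHCSQMPDGNVSPLATADQSSLEATYFTKGLAKERLTVGGVLDAYNALLKVVDEKSP
RNFSAQELYLAKQAGALILGPEVWLLTGSGRHNVASLIIAGPDQWYTSEYETTPLELGDD
SVEAGDENKKEQGKLVFRGTKLTQDDYAGVAEFCLNGDSSMDLPKTKLDM
>PROT0005
RGYRKKSEPRLTLLGVGQKVVAYNCLAMEIGNSVHNAIWDTPGSGTCDRKELGMRTANYL
SDTNTSTAREGHNPVAEISMLSPGCLTNAKINNVHKPTRLSLWGDSGTPLCSAWTGDTLD
LFKPVSELLYCLVKGMHVCECRGVTVGAIWSAQVWRTTIDRDIYMLVGYVIHDVEATNQR
ADLALRPPAFVDLAVEKMRVRIC
>PROT0006
RYASELLPYQKRLKILGFEKGSTHPVIMKPVDWQSPTHRGLQEASSQHPCQNPKFRLRIC
LPVTASGQIHLLQPQIQIPLMALFICPTIDPDTDILDGGRYISENKGSRDGSYPTYRPFI
PVGKAQKSFPQLEKREDLFSSVSPESRRQSGQLHHELIKTQQYFLDKVCRTLSKILEGGY
HFVDWTPKEDDIKVLYREMEAVHEDPLARGSLLLQYSALFDEFVRTQGKKGKSCGLQPRD
EGGRYQAGSVNIIPTHEADTPYAISQAKPQLEWLRLCFAEEKHISADSLKGLFTSHATGP
TSTLTLGLHSSEEILVVWRQGIASGCGHRAFVTPMFTSLEFI
>PROT0007
AKKGIHIPLESLLRRTSQREQGGDKAPRSDPSAEGLELHPLQFRRRAVNGKLLFGISKAL
EAYGLIAVVEKIEQSRQAFLQIKTAGGYFAKPESEQETERSGDNLLSLLLLKEGGFSDEL
GFILQYTKLKFVAEQNGVKNDTDKTVVSFALAWAHEALCVQITSHTVPIVVICTQFNGVH
EAHYFLYAGSDVSENMQGIFGEVTIQLGIWHNVGSDRSSYRYGLFCKRSAVFGSTRHLSI
SSLVIRPHLPLDYWAVL
>PROT0008
DSKRSLASQVGSTIKHAFHDSKNGIRLNKMVGLQCWLFSSPVCLRVPNINMVSRVASLRG
LSAGLTGSFGMPTTGRPISVLVDESGNLERREGSVTLIKELFEIALQPYTPVKSGLYNLS
GSAFEGVAGNQSIFTDAFLVRMLQPHDESPSAVIVNMSPQENICDLGSDAYGLFEKSASY
MIFEHTASQAARQGTFKDPCESLQRPEQDGKDDPRIIELNVAVYIRSPGPTDL
>PROT0009
TSARQDLQHLYPLADTRSNNLRHLLQFACETRRKDLTLPIEPLIGQGNGRILVRRHTIYV
PSLRDYSEFNSEWIYRLIDCPSVIVGVVETQQTLLITVESGEENGFDHSALNAGVYTESL
ELVTKAVYLFLQLIFGAGVARSKNFQRRLYTNQGVPTGYDLDESAIETCHTQQYAQRRRC
CSPGALDRHSDLD
>PROT0010
SMFWQHTIVGYARGKPAFDRFLHFVLPQSGCLEAVPKDSLEYVVSLGPEPAARHQSSPTP
VVAGIGETAESFGWSKDGYSARIRGDAGTTQREIVYKSVYGPILLGASQTEFNVLENVTV
KGTSTKGFTVITIKNFGGGLDSEKPDKMMTSDSMQ
>PROT0011
LQSSFSNQTKVTSILERTERQAVLGASHLEPKSQRGATVPVRPKILFKLAKGPSPQPGIT
VEAWTPSNVFKQFRGRSKYPRADRVPVATTPKQFQQLGAESFCFLNTTWTLEVFPGSEKF
TPPGETSRYMEPGLLMVSKSTSMVLDGPIKKEDAQHLVPSSVAIVLVEAVKLVFWKF
>PROT0012
FLLTAAEPSLPPAFYHVLFAFHKKMLAGWARLRHILVHCATGDNTNEKGAWLDTYSGELN
TWVHNDLCDDGGRCDPQRRQMRCFRELGKSQKGSPKTQYQVMRTDLPASRVILVKSKHGF
KESYDAAVCQGEFQATNFEPPGHLVLTPMLQLREHTKTVNDRQGTLAAFPSDAPKKSVWS
AENVCLKKGG
>PROT0013
DMKRPVHTIQSKKPDLDFPYYGELKISRMPNQVVYTDLSGPAEKCKFTGISMAFPEFPLG
MPAGGTAIEQSATQFVGSCLLVSMAKIYQKISDSQKRKEKACKSELYSVQNNNLIFAISM
ESAVPMKSAALGKLAYQDRLQRYDYLEIIVLARLSATTALDLCTEQPHFVAGHNIDNRQL
GALPKVESRVVFVKQVNN
>PROT0014
CNFIIYPREGTDVKILKLKQGEKCKLSDKSHSRAISLQYQMTKAGNVPGYKFMHDRQYDV
SGLPGDSELKVMKYIRFRRSLFPVGAEVAADTIQRKRLLGANGGTIDPLAIPGYSLVAFV
LENRNAAKACPKCTITPPKQFGTEIRHIVEFTGHTHYSTFFRSFEFDKLPAEDGEVIDQY
SPIKGSSLTPQGFFVSVSSKSEPAWTESS
>PROT0015
NKPTRFMMADIEFQWLPSQPATEELNRGVPTLCAPKKHELGTEWTISNLSSEVAALGKLL
VVIGPEKRASRIFLGSNGSPDKLVHKYKSDKETMFDKDLRGEIETDRHRSDRVNPHERSE
DIPIWSVNRVANESFRHPQVTKQEDRVRLPRNITIVSSSYYLIRWPAALSTILLDALLTE
TGLREVVWAPQTEDSGADPLRSAVTVSIFVKLQQQPLSKGVTREAVVGPAKQISVDQIEI
LVSAAYMPISMNFSFDNSGGENSDLLDLGEYDHPKATFKVWVKRTEWDPFFDVDVEHFYD
TGVRGLEKAQNGAVDHA
>PROT0016
IKLHFSGHLGRCHKGSIKLSFSVGESGFCPVTNKYQVQQQDGAVYPEDKKECPSAGGLNK
TKGSTTEELWPPHYEMQSSIGYMGDSTNIPYNSTRLEQSWEDPSCPGYICSGKDHDGNGQ
VNAVEILPHKPLGKIGNLKRSPHVDSKKTPYTDLSCLYFD
>PROT0017
HGKSLNDAVIVHPQCCKDGEGLGHLQAYKVAADVKTQCIHLRCVLIQGRKLEETNKSVEY
APGGLNKRVEFPKGLQVVSITREVFQQVQYAAENKCENKSLTRLIFGIIELDTMDHGELE
EQKQLLGKLHSFFHSTNIPSFQRKEPFILWECLVAPAMDPIPGCEGEELKSLLRTNALAN
A
>PROT0018
LETDPQGNHGGAQCECSLLNSPLGLYNLTAASVAAANDMQATGMIHKAKGIEHQYETPDA
TFDPRVLGGEPVCIICNYGRVGVRPEGDVSCLFSNVRDINVIEGFEHFLTVENQELEIHS
FLNHVHHQLREERITFFTIDFSGMSPRYGTMEDHDSMATNKELVNLPMPEEASAGNLVFD
ELGLQHQAMVVNYFGKLSKAQFTFGDGNGANRDKAAIGTAPR
>PROT0019
LFGAVADRLLGESDGRGVELLLSAMSAMKKLPQVPYQGECGDQQPILGVAHNETLIAGNG
ANGTQRTSHNGEEDFFQGAKEQFMELTGLKCATHQKSELMSAILNELQRFKGIIVAVACE
GTTVIAPVDSARLVTALFKAIKALTAVLFWLKITDFGATLNTL
>PROT0020
GLLGFIREYFGDKIQVFSGKDTIQAQFLQELSELEELLPTRHLQSQLDTGKTEVFCLSKT
KSDGDRLPFRYCGTTTFMCKNGKICASAYVYSADGEAVVSGTSHDDKSCKITEPHPSSTG
GDGDSAESSYIASGSAANQMLNDAIMFEKKGVVALFHACADPCTSGQVDMLGGCPEKVIG
VNNFPILKCTQVGGDGHEGGTKSAEVAALGEPPELLTAFNATWHSFVFAALAYPNPKTRK
GEGICVGLAMPCYE
>PROT0021
RHTFGQTTGLKQFSREGHVLPVKVGADQISLQINQILTVIATKWSITMRTNVKIPKRLRS
NVSTAAPHTKRFPVTILLHLWTGQVITSTCVYFPDNRRTGDSAFFSKSQTSTGIPNSSGD
RQGAAFGEAEIDEKTTKDGQKNRPTCGALPGALEEIVI
>PROT0022
RIKEESKGYTGKNEKGSDYFHCVSALKPHVFSGPKLLPAAYGIFPYKHIACAHYEMEASD
DSFEVESGNGHVVERDGCPRRSKEAKVKPVTRNFRKRFVESTETPNGHFKPRRIHSYFKG
YATSHQIPKVLSNIWEVYTPPVKSSTKPDCDRIVCESKFSFYGTLVGVGKPMQQGARNML
VGVEQVESGAKQGVAGHIGAEGQIRKHEFVLGFTQ
>PROT0023
SFRCQHQFIQVHEDQTAHEVDASYSDKLVRALSLQWYSNGEEPSTVGHELVRKETVSGKN
VFKAAFSQLKGSLCPYCYDGYYERPKSPFLRPLRDAAPKSYDIKMVNGQHMDMLPNNRDR
PQKCVSYLTTMVSDDKLPMTSDHTRAPDLYCSLYTAPTGQGEHGWFKLQWPTDQETNDTL
LCVLTCQILPSVETDAGGSMISVPPTGYEASEHLDKICNLESKATKDGG
>PROT0024
AHEFQEAEGENTSLSSPSIRLRRASAKNSAQHAHPCTAFHAVWVESHGQCAVISKDLECA
KGHWSRFRQLFEKGTLQVPEGVAFPTSRQIAPCSDAYENAYAQTGAAARLVPNEFYVKSR
GERWYIAGAYGTFVLSNSCCITVRNAVPPTFPQRDRVPEVDFTNHSPDFSSCLRHAKVRF
TQGGEKIGTSLWQVSPQSRTHIFVVKKDYQWPLRTTILVLSLSAADKIVYDSLTISALHG
GKLLRSWQGNKFHFLALKAGYNANQDKFLSFDDPALSSQAKFLEDVTDSAHYVLQITGEE
PMVESVRDECHREKAQDSPEQILM
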