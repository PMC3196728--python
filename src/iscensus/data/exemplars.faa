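>EX01_IS1 class=IS1 dde=60,138,183
MVATAPQNCWRLDQSCLIASSSAVGLRIEDGQYTNMYGREALYRVQRDWIQSTASLEEGVDFQDAPATQA
RLLDIRDVAVYKASQNDEGILSHAANGGVILSAHIVLMAYAILKLEFTQAALTFVVKAGSILKEYYRGDR
VTLLGLIRSQGVAPAGPEIPNAELIDAPFGDDAVQSSGFKEIMERIPLVKSTNARETAKEHVQRENGIHG
ILKWLAQGETDLLGMLNDFA
>EX02_IS5 class=IS5 dde=75,160,210
MQASIFPKELDNNIIRVERRLETMYRKIFAKVVGNKVILLLDVEYFSRDSTLQVAYLLQRTKAFHAITAD
QYPASDPGDSMAWEQTLVMTSNRKMAAANLDDSRPEFYGEEHCKVGRQETRHHDLLDGLCEISNTEAANN
GDVKEVQVDTTTDLKCQLKADVACMGMLRSAEDAQAESAIKLPKRKVYRTLLCQIIIVGHGCGTKIADRN
ERLRGISPGRITPPRRKEEDCASASQRLSTNDTKGLSQAASYGLKPVPNRIIVVQKTIVLLSQSN
>EX03_IS982 class=IS982 dde=70,150,205
MDLNMRVIQSIALAPRECHINDLVYCEVVSKEQGVSNLMYALQNLRDDERWSEEPKRPGKLIAIPTRGPI
DGHVYFTPTKNGLLKSMSAKRIWVKLRKFSGDFANVAQVIGVSGSLGQIRICFLSPYVQDKAFNLCVFIT
LIAWLLHPKEDVLGDNADGTSQAVEVRLEYNLIEGIYQGNLESDGHSVNVTPDEPKELERHNVEIEVCRD
YGAEAVQIEKPGHAQLVKALAILGMKFKPAKADGYGAPFATSPGCVDNKAKLIPLQHGGMYLPK
>EX04_IS110 class=IS110 dde=90,175,240
MSMTIYAAALGLKCKDEATTLHALRHRLPLRFLDVLPLLLQMLAALVMGQEGRFVNSPANAVNEVGVLRR
LLWIELLTGQLCRIQKDSLADKVDNGLAEHISQLEIKYTLIPAMSNFILHAKQDMVPYPEQIEEKAGQRA
NMQVRSGQLNQLESAGLLTEEVATKPCSKLGAVVFDFMFRPKIVAKRGDDETGVMKSYLFVADAITAINK
NTQHEQMLKKRMNQARQGPKRDMPTWIHQDESDGGYAYADDYGGKSHLPMKGASPHLIEVGLIGQFSQQD
SGQHFTATDDRLWAQYLLGRLGECMASDATAIFVMEHFTTPYSGNPALQEDASDHLAKLA
>EX05_IS200-IS605 class=IS200/IS605 huh=8,9,10,70
MIVDWNQVHLHKQPIPASHNKGATYAPDTGEPILNGRKALLTTAEVGAIIMFQYGRAKVGHAQGLSAQLP
YTIASTHGTGLPIHALLEKLGAVQSDKVHRDPEFNLKMSDKILCKRLNNHKADDVQCMVGIDEVRRAKKL
EYDAMKM
>EX06_IS481 class=IS481 dde=85,165,220
MLTDVAIFIQSFFLANFALTIEQCMADGYIIITLPTFWDGYSLHGPEETEGQASALGTMQLYKIVMLANK
SAVVFTPGFAKYADVDHRSSWEAVAGMSLGAHHHDCASKARASPHGDYLELRRVMAYRGRKSVTISVKGF
RANIASAKRKGPTLLKIRVAAEALPDYNLRVLETTPSFSQEESTHKNPSKKVLEQPTQDRFHERNAMAQL
KGVFTEPQKNELDEVDPERSLEWSDPQARKIGGKRGQVTHGHQQADQPLAVPAMSIAAVENYGSDKQEER
HAGFATRYGHQLLMIDKNMLMAGAHLDMGIELVL
>EX07_IS1182 class=IS1182 dde=110,200,260
MFTRPAFIVDDHDQGIGMAVELNFFSEQSASSPKNLYGRSERQANGPIQKIPRCMDDYRTKEVMKGDETG
YATSDFYPETLVEADGQAIGRIRLFTQLNEAGDAGKDDYVDVPLPLKAGQDVFNNVGSQSPHDLVSGAGS
SGYSSKAVQFRMDTTLPSMVQDAALLGFEIVGARDREVDLKLEENYQLVFVQNRDTLSNYDQFDYDEKGE
AGGGTHDDDVARVGEPDPALVVAEIHGFSPMKEKVEKLTYKTRGRWLELQECANWLEAVVNNLDKQVDKL
ALVCVYTSYPSPEINTAPDFWLTCKIGINFTPKEEAFTRKKPNEGYLILFNESQKMNFRSGLMMWSSVKI
KWGGYVDEAEDPDPVATVAPFQGILIMGPTVTAQDLEGSMISAGATKNEAGNLSSSKQAFIIYRMSMGLI
GQLVASLPIPKIRNSWVVAFAPLHDKKGWLENDVLMH
>EX08_IS6 class=IS6 dde=62,140,190
MRNEEAKLADGIPLIIACCDEAPRDANPLVPISYVEPKSVSLDGVDAWENQKKFIKYTELDLDNKRAPQR
KLGGAAIGFSQYQTNAYSMTLAAHIESPRYIRGSPARDVPGHIIRVREVRVVDAAICFTLEPIVTEILIF
DKNTSFDSRAGLINTENLTRHMYIKSEDVFEKGTIVMNRMGGWASTTLDNEKATLFAYLQTLFYRECADV
VILMILKQLLSMLNAIEKLMQLEHS
>EX09_Tn3 class=Tn3 dde=100,190,250
MGNPYYHPYGLMFIESIKISYGASVDCLLKILEIMDASIEQSSAMYSATETFDTNNHKTMLTIARPQSRM
AQGHKGFYGVEELVLLDLLASQTDRLDAASDKIKESPSRRDVEPRECGSLLRREQATLTDFKQMEIVVST
EFIHKIYVAVAAIEFNGRAPPHEYLVDCRTDSMSPTRPSYLEFIGLTDIADQDCRREFVIAIQKGAELGI
TTALTSRDTLRLPVNLERAAGVAEFYNSIVAKTSMMSAEEEKERLGQDSEADVKAPPTQFIPIPPAESSE
SWVALIDAGDMAGVEPTHMSKIAWRDDQWADADYDVQVMKRANKLLQGETNSRSLIVRDLAISSAKWFEL
IRCENEGERGAELHEGKTEVVVFGLTASILVVYAMAKAMDSNSMIGRSSA
>EX10_IS3 class=IS3 dde=80,170,225
MRPNEGILHIKVRTPYYLVCNLENKCGIEKTMHVATAIANLAENQLRENDQESANQKRIKGEAFMLTVAF
GEFATNEDVSDWLIAIVRFWNRIVALTIAGQFLMHDEGDAVMTSDLERPAKAPVEEAALDMYEPMVIDIY
LGDLLPDYSPPKLKKVGSGKRYYNHEQVVNDMRESSLFAIYQVSDNVVNMRLEFAFAANTSQIGTARQYD
VYPRGFQTIMRYGWSESEGQTKHAKAYSGGMMPNEKTEHMENHMMKYITRGARYGSGRRIKGINLAKMIL
YLDIHGKSFAGLRMMDADDD
>EX11_YhgA-like class=YhgA-like dde=78,168,230
MDGLLTLRPYKGGGGEEPHTVAHETPLVKFTDECYPAGRELECRIADLVLVSPAIFQSSMLNVIRRLQIG
KEKTPAEADLPPKKNQEFIMPTEYFTAKKQQLVSFQEKSLMIAINKNPEDRGFYQLKTAGYESHNISYSR
KDLVMELDDLWAANKVRIERRRRGGSVEDSESMLNDVAINWHSEIGWKTFDISTRKAGPCLHGLPLGSIT
VYPEPLKCERTRTVDAKNAAEVKLLSKLQSVGDGAVRVGLPFSRRSAGQNVTLIVVGDKLNTHIGREYTR
ENPQPIEGIQLQVNDAARLV
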