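>Beta_elim_lyase_seed1
NKGLAGITAVVKYSPLIATDSSTAVDAIENDICRRTTIPAKLEFSYDRVDYNVSTSDPGYIVTLNEGWRL
GFKQTTYHPWKEMLLDAQCLFKQLVIQETIDLCSDVGAYIKLRADAKSEVLNKEPVQDPKDWSVVKESWF
IQYKAYYTCFQSHGNWGESREVTASVSLEIIGVLYCDYMDIVSLQGPGWHLGSRFLRDLEICSDVLPGFD
SRNMSREHRSCKLIICNILVKASPANGDLLTVMDRGKTTFNEELLNDTVNADRANIVDDFARRSPRSEKT
KASIETDTHVRFSETNVATFEFNLTTLNACPSSKKESPSLQYASLRTSSIYNSNDLAGMTTTSKRNPWSF
VWLSVGTASMCTYYEKLLIDAEKKAYPNEPLVFGLAHNYAKVLKIPNDSTVVDYILSYFSTLVDSGMALN
PPRSDVKT
>Beta_elim_lyase_seed2
AKECALTFAVVKYSPCNATDSSIAVDAIEIDVCRWFTIPYVLEFSYDDVDYNVSTSGPGYINTWNETKWL
DIKQTSYHSWKEMLLQAQCLFRQAVVQITSDLGPDIGAYIKLRADLRSERYPRVSCKDPKDWSVVKESWF
IQAKAYYTLYFSHGVWDNTKIVTASVSLEIVGVLYCDYMDELTLLRPGWLAGTKTLRDLEICSDPLHGIK
PRVMDKEHYSLKLIFCNILVKATPINGDLLTVWDRGKPGFFEELLNDTVIADVANIVHDVYKRSSRSSKT
KATFFQCTHVRFSETVVATFESKATTLVALDYSKKESPSLQYASLITPSRYNPRDLFGGRTQKLGNHHSG
VWLSVGTASYCTEYARGLFDAAQKASPVEPLVTCLAHNYAESKRIPWDSTVIDYNLSITPDLNDSGMGLN
PPFSDVDT
>Beta_elim_lyase_seed3
NDGIALTFAVNRYSSCWATKSSIAVDAIEVDICRRTTIPPVLSFSYDDVDYNISTSDPGYIVTWNDTWRL
DFKQTTYDPWPEMCLQAQCLFKQASIQETSDLCSDIGAYIKLFADLRSEFLVRIPVKDPKDWSVVKEYWF
IVVKAYYFCYFSHGNWGATKIVLESVSLDIVGVLYCDYMDFFTLLRHGSASRTRILIDLEICSDTQHGIH
PINMTREHYSLKLIICNILVKASPVNQDILTVMDRGKYFFNGELLNDTVIADNENRVHDNYRLSCRSTKT
KLVGAQDTHVRGSETNVATFEFQLTVLKALPSPKKESPSLQYAVLISSSFYNRVDLTGMTTQSKGNHHSG
VWLSVGTASYCTMLARCGINAAKKAYPNEPLVFGLEHNYHRSKKIPWDSTVVDYRLSRFSDLVDSGMCLN
PPFSPVDT
>Beta_elim_lyase_seed4
FLTCALTVAVVKYPFCIATDSSIANDAIEIDACIRTTIPAVLAFSYDDVDYNVLTSDPGYIFTWVETWLL
KIKCTFYHMLKEMLEQAQCLFDQAVVQETVDLGNDICAYRKLRADLRSEITNRKPVKDPKGWSVVKESWF
ILYKEYYTVYGSWRVWGNTKVITASVSLEIVGVLYCDYMDAQSLAGPTWLLKTRFLRDLEICSDPLHLID
SKNMDREHYTLKLIICVTLVRLSNVNMDLLTVMDRGKSTINEEWTNDTVIADVANIRHDGYNRSTIPTKT
KLVVEFHTHVRFSETNVATFEFEATTLLALYSSRKEIPSLQYASLITSSRYNPTDLRGMTHQSKGNHHSL
VWLSVGTASYQWDYARCLIDLAKKAYPNEPLVFGLAHNSAKSDKIPWDSSCNGYDLSIKTDLNDSGMTLA
PPNTGVDT
>Beta_elim_lyase_seed5
NRGCELTTAVVLYSPCIATDSSIAVDAIEIDICRRTSIPEVLAMSYDDSDYNVSTSDPLETKTWLETWRA
IMKQTTYHPWKEMLLQAQCLPKQAVVQETVDLCSDRGAYVKLRADLRSAICRWIPVNDPKDWSVVKESRF
IQYKLYYTCYFSHGNWGNTKFVSESVSLEVVGVLYCDYMDEQTLAGDDQHLGTRILRDLEICSDDLHGID
YLNGDREHYSLKLIICNFLVKATPVNIDLQTVMDRDESFFSEELLNDRVIADVANFVHNNYRRSTRSTKT
KEVFAQDTHVRFSETNVATFEFKLVTLVALPTSRKESPSLQYASKKTSSRYNPVDLKGMTTQDKLNHHSG
VWLSVITASYCKMSERCLIDAAKKAYWNEPLVFGAAHNYLKYMKSPWMSIVVDYVLSRFSDLNDTGMMLF
PPFSDVDF
>Beta_elim_lyase_seed6
NKGQALTTAVEKYSPLIATKSSIAVDAIEIDICRGTTIPASLEGSYDDVDYNVSTSDPGYIVTWNETWWD
DTKQTTTHPFKEMLLQAQCLFRQAKVIESSDLLSDIGLSIKLWAELRSEICNRIPVKAPKDWSVVKISWF
IQYKLYYRLYTSHGNWLNFKFVTASVSLEIVGVLYCDYMAGQTLLGPGPAQGFEILRDLAICSDDLPGDD
ERVPDKEHYSLKLIICNILSRASPCNGDLLTVMDRGKSKFNEELLNDTVVADVDVIVARPAVRSTRSSRT
KEVFALDTHVIFSETNVATFEFKLTTLIACPSSKKESPSLQYAPLITSSLANASDLFGMTTQSKRVHASG
VWLSVGTASYCSMYARCLIDAAKKWYPNEPLVFGLAHNYYKYKRIPWDTTVVAYIQSRFSDLNDSGMCLN
PPFSYLDT
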