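>CP_seed1
GLIRESCAIVINMPKVCISFNELEQAKQGRGGDSLWRNGGPTKPGQTINRAEDEEVSQTPWDKENGYTAS
LDPLGAYPYA
>CP_seed2
GLQIESCAIVINMPKVCISFNEIESAKQGRGGDSLWRVGGPTKPGQTLNEDEDEEVSQFPWTKANAYTAS
ADPLFFTPYE
>CP_seed3
GLQIESCAEVINMPKVCISENEDETAKVGRGGDSLWDVGGPLKPGQTVNEIIDREVSQTPWDKANAYTAS
HDPLFEYPYR
>CP_seed4
GLQIHSCAEVRNMPKVQISNNEIEFAPQGRGGDSLWRLGGPTRPGQTLNEAEDEEVSQLVLDKANAYTGS
EDSLFEYPYG
>CP_seed5
GLYIESEAEIRNMPNVCISFNEIEKAKRGRGGDSLWRIGGPTKPLQTCPSAEDEGVSQTAWDKAKAYTAS
ADPLFAYPIA
>CP_seed6
GLQIEYLAEVVNMPRVGESANETIFANQGIGGDSLWFVGGPTKPGLTCNEAEKEECPGTPWDKANAYTAS
ADPLFCKPYA
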