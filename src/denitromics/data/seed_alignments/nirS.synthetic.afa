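>nirS_ref01 synthetic seed sequence 01
HWQI-SINPGIWSVDICYPFTTHQDL--SVRNYIKILQLHP-KIHCAGFCPTLQQLKYLTTFV-NICSFI
TLEMSWCRSIFLECGLPFICLCHFAQAEINYPHYRLHSAAAPMYTGWWGEDQCAHCFDVW
>nirS_ref02 synthetic seed sequence 02
HWQIDSINPGIWFVDICYQFTTHQDW-ASVRNYRYTLQLHPMCIQCAGFPVTLQQLKYLHIFVYNQASFI
TLEMSICRSDFLEHG-PFGCLCHFAQAEINYPHYQFKSAAKPKYPAWWGEDT-AHCFDVW
>nirS_ref03 synthetic seed sequence 03
HWQIDSINPGIWSVVTCIQFGTHQDL--SVANYIKILQLAP-CIRCAGVTVTLQQLKYLTYFVNNYNEHI
TLEKSWCRSIFLECF-PSGWLCHFAQAEINYPHYRLKSAAAPKYPAWWGEDQ-AHCFDVW
>nirS_ref04 synthetic seed sequence 04
HWQS-SINPGIWSVDICYQFGHHQDL--SQRNYIKILQLYL-CIHCAFFTVMLQQLKYLTIFV-NYVSFI
TLEMSWCRGIFLEFG-PFGCLCHFAQAEINYPGYRLKSAAAPKYPAWWGEDQCALCFDVW
>nirS_ref05 synthetic seed sequence 05
HWQIDSINPLIWSFDICYQFTTHQKLNASVRNYIKILVLHP-CIHCAGFTCTLQQLKYLTIFVNNFCSF-
TLEISWCRSIFLECG-PFGCLCAFAKTEINYPHYRLKSAANPKYPAWWKEDQ-AHCFDVW
>nirS_ref06 synthetic seed sequence 06
HWQIDSINPGIDSVDICYQFTTHHDL--SVRNYIKILQLHPMCWHPAGGHVTLQQLKYLTIFVNNYCSFI
TLEMSHCRSIFLECG-PFGCLCHFAQAEINYPHYRLKSAAAPKYPAWWGEGQ-AHFFDVW
>nirS_ref07 synthetic seed sequence 07
HWQIDSINKGIWSVDICYQKTTHQDL--SVRNLIKILQLTP-CIHCAGFTVGLQQLKYLSIFVNHYVSFI
TLEMSWCRSIFFECG-PFGCLCHFAQAEINYQHYSLKSAAAPKYPLWWGEDQ-AHCKDVW
>nirS_ref08 synthetic seed sequence 08
HGEIQDINPGIWSVDICYQFTTHQDLN-HVRNYCKILQLHP-CIHCAGFTVTLQQLKYLDIFVNNYCSF-
TLEMSWCRSIFLKCGLPFYCLCHFHIAEINYPHYRLKSAAAPKYPAWWGEDQ-ARCFDVW
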