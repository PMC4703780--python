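>pflB_ref01 synthetic seed sequence 01
RTHQGFEDQ-ESHRIKYP-TICQMSSVT-FYLEIIGRSNNANYGLQMC-YAMPWQLDRR-IMISYIGGDQ
QLIMAVNDPALGRIEGLVPLEIRIVPLLHTFLPRESPDFKH-SPPCPQIYREHKFGYRIW
>pflB_ref02 synthetic seed sequence 02
RTHQIFEDH-ESHRIKYP-TICIMSLKT-FYLEIIGKSNNANYGLQHC-YAMPEQVRRR-IVRSYIGGDQ
DLIMAVNDPALGRIEGLVWLEIRIQPLLHDFLPRKSEYFKH-SPPCPQIYRGEKFG-RIW
>pflB_ref03 synthetic seed sequence 03
RTHQGTEWH-ESHRSKY--TICDMSSVTSFYLEILGRSNNAEYGLQHC-YAMPEQLDRRTIVMSYITGDQ
DEIMAVNDHALGRIEGLVPLEVRIVPLLHDFLDRKWEYFKH-SPPCPQLYRGEKFGYRIW
>pflB_ref04 synthetic seed sequence 04
RTHQGFEDQ-ESHRIKY--TICIMSSVTSTYLEIIGRSINTNYGLQHC-YVMPEQLDRR-IVMSYIGGDQ
DLIMAVNDPALFRIEGLVPLEIRIVPLLHDSLPCKSEYFKH-SPPCDQIYRGEKFGYRIW
>pflB_ref05 synthetic seed sequence 05
RTHQGFEDQ-VSHRIKYP-TICIMSSVTSFYNEIQGRSNEANYELQHC-YAMPEQLDVR-IVVSYIGGDQ
DLIMAVNDPALGRIQGLVPLFIRIVPLKHDLLWQKSEYFKNTSPPCPQMYRGEKFNYRIW
>pflB_ref06 synthetic seed sequence 06
RTHQGLEDQIESHSIKYPFTICIMSSVTSWYDEIIRRSNNAKYGLTHCVYAMPEQLDRC-IQMSWIGGDQ
DLIMAVNDPALGRIEGLVPLEIRIVPLLHDFLPRKPEMFKH-SPPCPQIYRGEKFG-RIW
>pflB_ref07 synthetic seed sequence 07
RTHQGFEDQ-ESHRIKWP-TICIMSSVTSFYLYIIGRSNNANYGLQHCSYAMPEQLHRR-IVMSYIGGDQ
DLIMGVNDPALGRVEGLVPLEIRIVPLLHRGLPRESEYFKH-SPPCPQGYRREKFGYRIW
>pflB_ref08 synthetic seed sequence 08
RTHQGFEDQIESHRIKLPFTIMIMSSVTSFYLEIIGRSNNANYILQHC-YAMPEQLDRRTIVMSYHGGDQ
DLIKAVNDPAAGRTEGLVPLLIRIVPLLHDFLDRKSEYFKHNSPPCPQIYRGEKMPYRIW
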