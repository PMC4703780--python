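>nirK_ref01 synthetic seed sequence 01
KEMNFT-GCQPLHVTNPSCFTWKHT-YMLWQYNWDENNYAGWKDHPTCHRPNLDV-HMGLIMYYGYRGHC
GGLTNGYDTPPQCEVCSEFFSITNYWDHEQQQVGSNQRVYLKPAYHNTVIDSACIFVPCF
>nirK_ref02 synthetic seed sequence 02
KEPNFTGGCQPLHVTNPYCFEDKHT-YMLWQYYWDRNNYRSWQDHPTCHRPILDVDHMGLIMYYGYRGWC
GGLT---DTPPQLEVCSEFFSITNYWNHEPQQVGINQYVYLKNTYHNTVIDSICIFVPCF
>nirK_ref03 synthetic seed sequence 03
KPMNFTGGCQPLHVTNPYCFEDKHT-YPLWQYNWDENNYPGWQDHPMCHRPNLDTDH-GLIMYYKYRGWC
GGLSNG-DSPPQYEVCSEFFSKTSYWNHYPQQVGSNQYVYLKPTYHNTVIDSICIFVPCF
>nirK_ref04 synthetic seed sequence 04
KESNFTGWCQPLHVTNPYCFEDKHT-YMLWQYNWDENNYRGWQDHPTCHRPNLDT-H-GLIMYYGWRGWC
GGLT--YDTPPQYEVMSEFFSITNYWNHEPQQVGSNQYVYLFPTYHNTKISSICIFVPCF
>nirK_ref05 synthetic seed sequence 05
KEMNFTGGCQPLHVTMPYCFEDKHTSYMHWQYGWDENNYRGWQDHPTCIRPNLDT-H-GCIMYYGYRGWC
GGLT--RDTPPQYEVCSEFFSITNYWNHEPVQVGSNLYVYLKPTYHNTVRDSICIFVPQF
>nirK_ref06 synthetic seed sequence 06
KGMNFTGGCQPLHVTNPYCCEDKHC-YMLWQYNWDENNYRGWQDHPTCHRPNLDT-H-GHIMYYGYRGWK
DGLF--YDPPPQYEVCSEFFSITNYWNHQPQQFGSNQYVYLSHRYHNTVIDSICIFVPCF
>nirK_ref07 synthetic seed sequence 07
KHMNFRGGCY-LHVTNPYMFEDKHT-YMLWQYNWDENNYRGWQWHPTAHRPNLDT-H-GLIMYYGYRGWC
PGLT--YDTPPQYEVCSEFFSITNYFCHEPQQVNSIQYVYLKPTYHNTVIDSTCIFVPCF
>nirK_ref08 synthetic seed sequence 08
KEMNFT-GCQ-LHSTNPYCFEDKHTSYMLWYYNWDENNYRGWQDHPTCHRPNLDF-H-GLIMYYGYRGWC
GGLT--YDTPPQYEVCSEFFSITNFWNHEPQQVGKNQYVYLKPTSHNTVIDSREIFVPCF
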