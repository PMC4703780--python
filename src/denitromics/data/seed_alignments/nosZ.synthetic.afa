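>nosZ_ref01 synthetic seed sequence 01
IHFFREMVKVHHCGNQPRTKELMRAKDYVHHDSGHCSPAPMEYALTKIHFQKAEQCEAVANPKHHRTLHP
IFGDAQWGPT---YCEWDREVYEQNNGHVEW-VTCLMYFAKVGSKYAEIFNLWMPELRQW
>nosZ_ref02 synthetic seed sequence 02
NHCFREMVMVHDCGNQPRTKE-MRAGAYVHRDSGHQSWAPMEYALDKIHFQKCEQCCAVANPKHHG-LHP
IFGDAQWGPT-M-YPEWDREVYEQNNGHVEA-VTCLMYFAKVGEWYAEIFNLNMPELRQW
>nosZ_ref03 synthetic seed sequence 03
LHCFREGVMVFDCGNQPRTKE-MRAKAYVSHDSGKCSWGPMEYALTKIHHQKADQCETVANPKHHS-LHP
IFGDAQWTPT---YCEWDRFVEEQNNGHVQWKVTCLMYFAKVGEWYAAQFNTWMPELRQW
>nosZ_ref04 synthetic seed sequence 04
NHCFREMVMVHDCGNQPRTKA-MRAKEYVHHDSRHCSW-PMEYALGKIHFQKAEQCCAWANPKQCG-LTP
IFGMAQPGPT-M-YCEWDYEVYPQNNGHVEWAVTDLMYFAKVGEWYAEICNLWMPELRQW
>nosZ_ref05 synthetic seed sequence 05
LHCFREMVMVHDCGNQPRTKE-MRAKAYVVHDSGHCSWAPMEYALTKIHFQKAEQCAAVANPKHHG-LHP
IFGDAQWSPT--WYNEWDCEVYEQNNPHVEWAVTCLMYTAKVGEWYAEAFNLWMPELRQL
>nosZ_ref06 synthetic seed sequence 06
NHCFRGFVMVHDCGNQRRTKW-MRMKAYVHHDSGHC-RARMEYALTQIHFQKAESCEAVANPKHHV-LHP
ITGDNQWGPTK-WGCEWDREVYEQNFGHVEWACTCLMYGAKVGEWYAETFNLWMPERRQW
>nosZ_ref07 synthetic seed sequence 07
NHCFREMVMVHICGNQPRTKELMRFKFYEHHGSYHPSWAPMEYAMTKIHFQKAEQCEAVANPKHHGTLHP
IFGDAQWGPTK--YCEQDREVYEWNNGHSEWAVTCLMYFAKVEEWVAEIFNLWTPELRQW
>nosZ_ref08 synthetic seed sequence 08
NHCFREMVMVHDCGNQPRTEE-MQAKAYVHHDSGHC-W-PMEYALTKIHSQKAEQCFAVANPKHHI-LHP
IFGDHQWGPT---YCEWDREVYEQNASYVEWAVTCKMYFAKVGTWCEEIFNLWWPELRQW
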