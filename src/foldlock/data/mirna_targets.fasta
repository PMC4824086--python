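>miR-21 hsa-miR-21-5p MIMAT0000076
UAGCUUAUCAGACUGAUGUUGA
>miR-18a hsa-miR-18a-5p MIMAT0000072
UAAGGUGCAUCUAGUGCAGAUAG
>miR-27b hsa-miR-27b-3p MIMAT0000419
UUCACAGUGGCUAAGUUCUGC
>miR-200c hsa-miR-200c-3p MIMAT0000617
UAAUACUGCCGGGUAAUGAUGGA
>miR-125b hsa-miR-125b-5p MIMAT0000423
UCCCUGAGACCCUAACUUGUGA
>miR-221 hsa-miR-221-3p MIMAT0000278
AGCUACAUUGUCUGCUGGGUUUC
>miR-451 hsa-miR-451a MIMAT0001631
AAACCGUUACCAUUACUGAGUU
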