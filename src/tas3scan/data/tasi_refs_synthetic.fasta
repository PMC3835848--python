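>tasiARF_ref kind=ARF note=synthetic_standin
TTCTTGACCTTGTAAGACCCC
>tasiAP2_ref kind=AP2 note=synthetic_standin
TGGCATGATCTTGATCCAGCT
>AP2_target_ref kind=AP2_TARGET note=synthetic_standin
AGCTGGATCAAGATCATGCCA
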