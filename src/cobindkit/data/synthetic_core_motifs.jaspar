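>CTCF_like CTCF_like
A [  1  1 18  1  1 18  2  2  1  5  2 18  1 18  2 ]
C [ 17 17  1 17 17  1  2  1  1  5  2  1 17  1 17 ]
G [  1  1  1  1  1  1 15 16 17  5 15  1  1  1  1 ]
T [  1  1  0  1  1  0  1  1  1  5  1  0  1  0  0 ]
>ERE ERE
A [  1  1  1  1 17  5  5  5  1  1 17  1  1 ]
C [  1  1  1 17  1  5  5  5  1  1  1 17 17 ]
G [ 17 17  1  1  1  5  5  5  1 17  1  1  1 ]
T [  1  1 17  1  1  5  5  5 17  1  1  1  1 ]
>FOXA1_forkhead FOXA1_forkhead
A [  1  1  1  1  1 17  1  2 ]
C [  1  1  1  1  1  1 17  2 ]
G [  1 17  1  1  1  1  1  2 ]
T [ 17  1 17 17 17  1  1 14 ]
>MYF_ebox MYF_ebox
A [  1  17  1  1  1  1 ]
C [ 17   1  1 17  1  1 ]
G [  1   1 17  1  1 17 ]
T [  1   1  1  1 17  1 ]
>AP1_like AP1_like
A [  1  1 17  1  1  1 17 ]
C [  1  1  1 17  1 17  1 ]
G [  1 17  1  1  1  1  1 ]
T [ 17  1  1  1 17  1  1 ]
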