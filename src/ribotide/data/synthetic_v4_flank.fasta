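>flank_01 synthetic variant of the conserved 515F-region motif (Y=C, M=A)
GTGCCAGCAGCCGCGGTAA
>flank_02 synthetic variant (Y=C, M=C)
GTGCCAGCCGCCGCGGTAA
>flank_03 synthetic variant (Y=T, M=A)
GTGTCAGCAGCCGCGGTAA
>flank_04 synthetic variant (Y=T, M=C)
GTGTCAGCCGCCGCGGTAA
>flank_05 synthetic variant (Y=C, M=A)
GTGCCAGCAGCCGCGGTAA
>flank_06 synthetic variant (Y=C, M=C)
GTGCCAGCCGCCGCGGTAA
>flank_07 synthetic variant (Y=T, M=A)
GTGTCAGCAGCCGCGGTAA
>flank_08 synthetic variant (Y=T, M=C)
GTGTCAGCCGCCGCGGTAA
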