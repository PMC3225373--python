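>miR156/157
UUGACAGAAGAUAGAGAGCGC
>miR159
UUUGGAUUGAAGGGAGCUCUA
>miR160
UGCCUGGCUCCCUGUAUGCCA
>miR164
UGGAGAAGCAGGGCACGUGCA
>miR166
UCGGACCAGGCUUCAUUCCCC
>miR166*
GGAAUGUUGGCUGGCUCGAGG
>miR167
UGAAGCUGCCAGCAUGAUCUA
>miR168
UCGCUUGGUGCAGGUCGGGAA
>miR168*
CCCGCCUUGCAUCAACUGAAU
>miR171
UGAUUGAGCCGUGCCAAUAUC
>miR172
AGAAUCUUGAUGAUGCUGCAU
>miR390
AAGCUCAGGAGGGAUAGCGCC
>miR396
UUCCACAGCUUUCUUGAA
>miR396*
GUUCAAGAAAGCUGUGGGACA
>miR482
UUUCCUAUUCCUCCCAUACCGA
>miR845
AGGCUUUGAUACCACUUG
>miR858
UUCGUUGUCUGUUCGACCUUA
>miR894
UGUUUCACGUCGGGUUCACCA
>miR1310
GAGGCAUCGGGGGCGCAA
>miR2911
GCGGCCGGGGGACGGACUGGG
>miR4342
CUAAGGAUGUAGGGUGGU
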