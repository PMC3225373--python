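sequence	length	family	juvenile	adult
UUGACAGAAGAUAGAGAGCGC	21	miR156/157	N	1
UUUGGAUUGAAGGGAGCUCUA	21	miR159	109	4
UUCGGAUUGAAGGGAGCUCUA	21	miR159	1	0
UUUGGAUUGAAGGUAGCUCUA	21	miR159	1	0
UUGGUAUUGAAGGGAGCUCUA	21	miR159	1	0
UUUGGAUUGAAGGGAGCUUUA	21	miR159	2	0
UUUUGGAUUGAAGGGAGCUCUA	22	miR159	1	0
CUUUGGAUUGAAGGGAGCUCUA	22	miR159	1	0
UUUGGAUUGAAGGGAGCUCUAA	22	miR159	1	0
UUUGGAUUGAAGGGAGCUCU	20	miR159	4	0
UUGGAUUGAAGGGAGCUCUA	20	miR159	3	0
UUUGGAUUGAAGGGAGCU	18	miR159	8	0
UGCCUGGCUCCCUGUAUGCCA	21	miR160	3	2
UGGAGAAGCAGGGCACGUGCA	21	miR164	8	1
UGGAGAAGCAGGGUACGUGGA	21	miR164	2	0
UGGAGAAGCAUGGCACGUGCA	21	miR164	1	0
UCGGACCAGGCUUCAUUCCCC	21	miR166	1	0
UCGGACCAGGCUUCAUUCCUC	21	miR166	2	0
UCUCGGACCAGGCUUCAUUCC	21	miR166	1	0
UCGGACCAGGCUUCAUUCC	19	miR166	0	1
UCGGACCAGGCUUCGUUC	18	miR166	0	2
GGAAUGUUGGCUGGCUCGAGG	21	miR166*	1	0
GGAAUGUUGUCUGGCUCGAGG	21	miR166*	0	1
GGAAUGUUGGCUGGCUCGAGGC	22	miR166*	1	2
UGAAGCUGCCAGCAUGAUCUA	21	miR167	2	1
UGAAGCUGCCAGCGUGAUCUA	21	miR167	1	0
UGAAGCUGCCAGCAUGAUCUGG	22	miR167	2	0
UGAAGCUGCCAGCAUGAUC	19	miR167	13	1
UAAAGCUGCCAGCAUGAU	18	miR167	1	0
UCGCUUGGUGCAGGUCGGGAA	21	miR168	7	1
CGCUUGGUGCAGGUCGGGAAC	21	miR168	1	0
CCCGCCUUGCAUCAACUGAAU	21	miR168*	1	0
UGAUUGAGCCGUGCCAAUAUC	21	miR171	1	0
AGAAUCUUGAUGAUGCUGCAU	21	miR172	1	0
AGAAUCCUGAUGAUGCUGCAU	21	miR172	1	0
AAGCUCAGGAGGGAUAGCGCC	21	miR390	0	1
AGCUCAGGAGGGAUAGCGCC	20	miR390	2	0
UUCCACAGCUUUCUUGAA	18	miR396	4	0
GUUCAAGAAAGCUGUGGGACA	21	miR396*	1	0
UCUUACCAAUGCCUCCCAUCCC	22	miR482	1	0
UUUCCUAUUCCUCCCAUACCGA	22	miR482	0	2
AGGCUUUGAUACCACUUG	18	miR845	2	0
UUCGUUGUCUGUUCGACCUUA	21	miR858	3	1
UGUUUCACGUCGGGUUCACCA	21	miR894	1	0
GAGGCAUCGGGGGCGCAA	18	miR1310	1	0
GCGGCCGGGGGACGGACUGGG	21	miR2911	1	0
CUGGCCGGGGGACGGACUGGGA	22	miR2911	1	0
GUGGCCGGGGGACGGACUGGGA	22	miR2911	1	0
UCGGCCGGGGGACGGACUGGGA	22	miR2911	0	1
GCCGGGGGACGGACUUGGA	19	miR2911	2	0
CUAAGGAUGUAGGGUGGU	18	miR4342	1	0
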