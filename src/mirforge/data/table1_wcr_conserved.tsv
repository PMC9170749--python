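family	member	mature_seq	ncr_flag
bantam	dvi-bantam	UGAGAUCAUUGUGAAAGCUGUUU	1
let-7	dvi-let-7	UGAGGUAGUAGGUUGUAUAGU	1
mir-iab-4	dvi-mir-iab-4	ACGUAUACUGAAUGUAUCCUGA	1
mir-1	dvi-mir-1	UGGAAUGUAAAGAAGUAUGGA	1
mir-2	dvi-mir-2a	UCACAGCCAGCUUUGAUGAG	1
mir-2	dvi-mir-2b	UCACAGCCAGCUUUGAUGAG	1
mir-2	dvi-mir-2c	UCACAGCCAGCUUUGAUGAG	1
mir-7	dvi-mir-7	UGGAAGACUAGUGAUUUUGUUGUU	1
mir-8	dvi-mir-8	UAAUACUGUCAGGUAAAGAUGUC	1
mir-9	dvi-mir-9a	UCUUUGGUGAUCUAGUUGUAUG	1
mir-9	dvi-mir-9b	UCUUUGGUUAUCUAGCUGUAUGA	1
mir-9	dvi-mir-9c	UCUUUGGUGAUCUAGUUGUAUG	1
mir-9	dvi-mir-9d	UCUUUGGUGAUCUAGUUGUAUG	1
mir-9	dvi-mir-9e	UAGUACUUUAGCUGUAGAUCC	1
mir-10	dvi-mir-10	UACCCUGUAGAUCCGAAUUUGU	1
mir-11	dvi-mir-11	CAUCACAGGCAGAGUUCUAGCU	1
mir-12	dvi-mir-12	GGAGUAUUACAUCAGGUACUGGU	1
mir-13	dvi-mir-13a	UAUCACAGCCACUUUGAUGAGCU	1
mir-13	dvi-mir-13b	UAUCACAGCCAUUUUGACGAGU	1
mir-14	dvi-mir-14	UCAGUCUUUUUCUCUCUCCUAU	1
mir-29	dvi-mir-29	UAGCACCAUUCGAAAUCAGUUC	1
mir-34	dvi-mir-34	UGGCAGUGUGGUUAGCUGGUUGUG	1
mir-71	dvi-mir-71	UCUCACUACCUUGUCUUUCAUG	1
mir-87	dvi-mir-87	GUGAGCAAAGAUUCAGGUGUAU	1
mir-92	dvi-mir-92a	UAUUGCACUAGUCCCGGCCUAU	1
mir-92	dvi-mir-92b	AAUUGCACUUGUCCCGGCCUGC	1
mir-92	dvi-mir-92c	UAUUGCACCAGUCCCGGCCUGA	1
mir-100	dvi-mir-100	AACCCGUAGAUCCGAACUUGUG	1
mir-124	dvi-mir-124a	UAAGGCACGCGGUGAAUGCCA	1
mir-124	dvi-mir-124b	UAAGGCACGCGGUGAAUGCCA	1
mir-124	dvi-mir-124c	UAAGGCACGCGGUGAAUGCCA	1
mir-125	dvi-mir-125	UCCCUGAGACCCUUACUUGUGA	1
mir-133	dvi-mir-133a	UUGGUCCCCUUCAACCAGCUGU	1
mir-133	dvi-mir-133b	UUGGUCCCCUUCAACCAGCUGU	1
mir-137	dvi-mir-137	UAUUGCUUGAGAAUACACGUAG	1
mir-184	dvi-mir-184	UGGACGGAGAACUGAUAAGGGC	1
mir-190	dvi-mir-190	AGAUAUGUUUGAUAUUCUUGGUUG	1
mir-193	dvi-mir-193	UACUGGCCUGUUAAGUCCCAAG	1
mir-210	dvi-mir-210	CUUGUGCGUGUGACAGCGGCU	1
mir-219	dvi-mir-219	UGAUUGUCCAAACGCAAUUC	1
mir-252	dvi-mir-252	CUAAGUACUAGUGCCGCAGGAG	1
mir-263	dvi-mir-263a	AAUGGCACUAGAAGAAUUCACGC	1
mir-263	dvi-mir-263b	UUGGCACUGGAAGAAUUCACAGA	1
mir-275	dvi-mir-275a	UCAGGUACCUGAAGUAGCGCG	1
mir-275	dvi-mir-275b	UCAGGUACCUGAAGUAGCGCG	1
mir-276	dvi-mir-276	UAGGAACUUCAUACCGUGCUCU	1
mir-277	dvi-mir-277a	UAAAUGCACUAUCUGGUACGACA	1
mir-277	dvi-mir-277b	UAAAUGCACUAUCUGGUACGACA	1
mir-279	dvi-mir-279a	UGACUAGAUCCACACUCAUUAA	1
mir-279	dvi-mir-279b	UGACUAGAUGGAACACUCGCCU	1
mir-281	dvi-mir-281a	AAGAGAGCUAUCCGUCGACAGU	1
mir-281	dvi-mir-281b	AAGAGAGCUAUCCGUCGACAGU	1
mir-282	dvi-mir-282	UAGCCUCUCCUAGGCUUUGUCU	1
mir-283	dvi-mir-283	AAAUAUCAGCUGGUAAUUCUGGG	1
mir-305	dvi-mir-305a	AUUGUACUUCAUCAGGUGCUC	1
mir-305	dvi-mir-305b	AUUGUACUUCAUCAGGUGCUC	1
mir-307	dvi-mir-307a	UCACAACCUCCUUGAGUGAGC	1
mir-307	dvi-mir-307b	UCACAACCUCCUUGAGUGAGC	1
mir-315	dvi-mir-315	UUUUGAUUGUUGCUCAGAAAGCC	1
mir-317	dvi-mir-317a	UGAACACAGCUGGUGGUAUCUCAGU	1
mir-317	dvi-mir-317b	UGAACACAGCUGGUGGUAUCUCAGU	1
mir-750	dvi-mir-750a	CCAGAUCUAACUCUUCCAUGCGA	1
mir-750	dvi-mir-750b	CCAGAUCUAACUCUUCCAUGCGA	1
mir-927	dvi-mir-927	UUUAGAAUUCCUACGCUUUACC	1
mir-927	dvi-mir-927b	UUUAGAAUCUGUACGCUUUGUU	1
mir-929	dvi-mir-929	AAAUUGACUCUAGUAGGGAGU	1
mir-932	dvi-mir-932	UCAAUUCCGUAGUGCAUUGCAGU	1
mir-965	dvi-mir-965	UAAGCGUAUAGCUUUUCCCCU	1
mir-970	dvi-mir-970	UCAUAAGACACACGCGGCUGU	1
mir-971	dvi-mir-971	CACUCUAAGUUUGAACACCAAGC	1
mir-980	dvi-mir-980	UAGCUGCCUUUUGAAGGGCAAU	1
mir-981	dvi-mir-981	UUCGUUGUCGACGAAACCUGCA	1
mir-989	dvi-mir-989	UGUGAUGUGACGUAGUGGUAUG	0
mir-993	dvi-mir-993	GAAGCUCGUCUCUACAGGUAUCU	1
mir-995	dvi-mir-995	UAGCACCACAUGAUUCAGCUUA	1
mir-998	dvi-mir-998	UAGCACCAUGGGAUUCAGCUC	1
mir-1000	dvi-mir-1000	AUAUUGUCCUGUCACAGCAGU	1
mir-1001	dvi-mir-1001a	ACAGCUUUAAAAUCCCAAGGAUCCU	0
mir-1001	dvi-mir-1001b	ACAGCUUUAAAAUCCCAAGGAUCCU	0
mir-1175	dvi-mir-1175	UGAGAUUCAACUCCUCCAACUUAG	1
mir-2514	dvi-mir-2514a	AUUCAUUACAGUGGUCCUCUGUGCU	0
mir-2514	dvi-mir-2514b	AUUCAUUACAGUGGUCCUCUGUGCU	0
mir-2514	dvi-mir-2514c	AUUCAUUACAGUGGUCCUCUGUGCU	0
mir-2514	dvi-mir-2514d	AUUCAUUACAGUGGUCCUCUGUGCU	0
mir-2765	dvi-mir-2765	UGGUAACUCCACCACCGUUGGCG	1
mir-2779	dvi-mir-2779a	AUCCGGCUCGAAGGACCA	0
mir-2779	dvi-mir-2779b	AUCCGGCUCGAAGGACCA	0
mir-2779	dvi-mir-2779c	AUCCGGCUCGAAGGACCA	0
mir-2779	dvi-mir-2779d	AUCCGGCUCGAAGGACCA	0
mir-2779	dvi-mir-2779e	AUCCGGCUCGAAGGACCA	0
mir-2779	dvi-mir-2779f	AUCCGGCUCGAAGGACCA	0
mir-2788	dvi-mir-2788	CAAUGCCCUUGGAAAUCCCAA	1
mir-2796	dvi-mir-2796	GUAGGCCGGCGGAAACUACUUGC	1
mir-2944	dvi-mir-2944a	UAUCACAGCCAGUAGUUACCU	1
mir-2944	dvi-mir-2944b	UAUCACAGCCAGUAGUUACCU	1
mir-2944	dvi-mir-2944c	UAUCACAGCCAGUAGUUACCU	1
mir-3049	dvi-mir-3049	UCGGGAAGACAGUUGCGGCGGAUU	1
mir-3477	dvi-mir-3477a	UAAUCUCAUUUGGUAACUGUGA	1
mir-3477	dvi-mir-3477b	UAAUCUCAUUUGGUAACUGUGA	1
mir-3849	dvi-mir-3849	ACAUUUUAACCAUAGUGCUGUU	1
mir-6012	dvi-mir-6012	UUCGGCGAUAAGAUCAGCCUGU	1
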