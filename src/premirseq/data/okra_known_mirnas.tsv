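mirna_id	mature_seq	precursor_seq	reported_mfei
miR156	TTGACAGAAGATAGAGAG	TTGACAGAAGATAGAGAGCACCCTCTCTCTCTCTCCCTGTCTGCCTTTCTGTCTGTCTTATTATTGACACGGCTGATGACTTGTAAATTCTCCATGAGAATCAGTT	-0.696
miR482a	TCTTTCCTACTCCTCCCA	TCTTTCCTACTCCTCCCATTCCAGGGACGGAGGAGGCTAGGT	-0.750
miR6300	GTCGTTGTAGTATAGTGGT	GTCGTTGTAGTATAGTGGTAAGTATTCCCGCCGCATATGATGCAACGATTCTTATCCTATACACT	-0.659
miR157	TTGACAGAAGATAGAGAGCA	TTGACAGAAGATAGAGAGCACCCTCTCTCTCTCTCCCTGTCTGCCTTTCTGTCTGTCTTATTATTGACACGGCTGATGACTTGTAAATTCTCCATGAGAATCAGTT	-0.696
miR159	GGATTGAAGGGAGCTCTA	TTTGGATTGAAGGGAGCTCTATTCTGTGATGAAGCAATTTTATTGTGGACTAGAGTTTCTGATCTGG	-0.769
miR396	CACAGCTTTCTTGAACTT	TTCCACAGCTTTCTTGAACTTGCGAGTCAACGGGTTAGCAAACCCGCAAGGCGCAAGGAAGCTGATTGGCGGGATCCCTCGCGGGTGCACCGCCGA	-0.750
miR6424	TGGTGCCACGCTGTGTGCG	AGAGCTGAATGTGGTGTTTTGGGCTCATGCTTGCGTGGTGCCATCAAAACTTGGCATTGGAGAAGCGGTGATGGTGCCACGCTGTGTGCGACTGA	-0.696
miR168	TCGCTTGGTGCAGGTCGG	TCGCTTGGTGCAGGTCGGGAAATTACGATAGGTGTCAAGTGGAAGTGCA	-0.604
miR160	TGCCTGGCTCCCTGTATG	TGCCTGGCTCCCTGTATGCCACAATGTAGGCAAGGGAAGTCGGCAAAATGG	-0.775
miR530	TGCATTTGCACCTGCACC	TGCATTTGCACCTGCACCTTCTCATTACGATAGGTGTCAAGTGGAAGTGCA	-0.878
miR166	TCTCGGACCAGGCTTCAT	TCTCGGACCAGGCTTCATTCCCGAAGCCTGCCCAGCAGAACGACCCGCGAACGTGTTATCGAAAAAC	-0.463
miR535	CAACGAGAGAGAGCACGC	TGACAACGAGAGAGAGCACGCAGCAATGAGGTTAATCGTGCTTCTCTGATGATTGGGTTAT	-0.571
miR162	TCGATAAACCTCTGCATC	TCGATAAACCTCTGCATCCAGGAGCAATGAGGATAATCTGCTCTTGTGATGATAGGGTTATC	-0.881
miR408	CACTGCCTCTTCCCTGGCT	TGCACTGCCTCTTCCCTGGCTTTCAGGTCTCCAAGGTGAACAGCCTCTGGTCGATGGAACAATGTAGGCAAGGGAAGTCGGCAAAATG	-0.646
miR167	GCTGCCAGCATGATCTTA	TGAAGCTGCCAGCATGATCTTACATTACGATAGGTGTCAAGTGGAAGTGCA	-0.339
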