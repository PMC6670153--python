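>synthetic_lncRNA_standin chr21:36209800-36212400(+)
AAAAATGCGTGTCGGGTCTCTAGCCATTAAACATACAGAGTAGAGTCCAGGCCCATGCTTGAGAACAAGTATAAACAAGCTCTTCAATGTGGGGGTGCTTGAATGTCGGGACACATTTCGCGATCAGGTGTATTGGTACACCATAGTAACTTTTGTTCGAATTGGATGAACAGTTAACGGTTGGAGAAGTCTTGCACCATTACCGTGCACCTAACATTATTGTATAGGTAAGACGGATGTAGGGATTATCCGAACGGCATAGGGGCTCGGGTCATATGTAAGATTAATACAGACTGCAATATTTCGAACCGTTCAACGTGGAACAGCGTTTGTGGGCATCCCACATGTGCTATTGATTGGAGATGTGGACACTTTTTGAGAGCACTGACGAGTGCGCAGCTTGAATATGAGCCTCGAGGTAACCCAATAGGTCTTATCAGATTCAGGTCAGATTCGTTCGACAACTCTAATAAACGCTACATTACTCCACAGTATCCTGCACAGGGACTGATGAGTAAACAAGACGGATTTGGCACTTTTAATACATTGCGGAATCTACACTAGTGTATACAGCAATTGTAGCGATTGAACGGTTTAACATACAATAGGTGGGACAGCCACACAACCAACTTTATTGCCACTTAATGGCATCGTACAACATCGGCTATATAGAGGCGTTGGGATAAGTCGATATGCCCATATAAAAGAACAGAAGCTCGACTTCCTATTTGGAAAGCACAATCGTCACCATGGAGAAACGTTTAGCGCACCGGACTACATACGAATGAGTAGTTCAATTGGAGTTCGGACTGGCCTGTCACTGCCGTGCAATAGCAATTAGAAGTTAGAAGTCACTTCGAGATTCATGAGGAATAGGTAGCCTGTTTTCCCCCTCTGGCGAAGCAATCCTCTGAGGATTTACTCACATACCCTACGTAATCATACTTGTAGATGACTATGTTACTAACGGTGCCGCACTTCATTACTCTCAGCCACTTCCAGATGGTTGAGCGTTGTAGGACTTTTTGAGAAAAAAGATATATGCAAGATCTGCAAATAATCTCAGGTCTATCTGTGACAGTTCATTCGCCTGGGCGTTGTATATCTCGGATCTTTTTAGCGTGCGCATGGATGGATGAGGTGTAACTCTACTAAAGTCGATAATTTGCTCACATACATAAAAGTTGACCCTAGCTGACAATCGCTGCTTCAAGCCACTTGTCAATTTCGCATATATTGCATGGGATGATCATCAATAGAAGCTACCCATTCCAAGGGCGATTAGCAGATCATAAACAGCCCATCGTTGCTAGGACGGTGCTCTGCCCGCTAATTTTCGTAACTAAAACCTGGCCCTATTAGCCTCAACGGATCATGTAACAGGAAGATTAGATACATTAATTCTTCCTGGTACCGCTTACGGACAGAGGTCAATCGAGAGGAGCTATTTCAGACGGTAGCAAATATCATTTACGCTATAATCCCTATTCCTCATTCACGCGCTGCTACATGCGAGGTTAGGGGCAGCTGAATCTTTACCGCTCTGACGTCACATAAGCGGCTTTCGTTAGTTCGAGAAGTCGGGGGATATTCCCTCCATCCATCTTTAGGTAACGGGACAACAATGGAACCTGCCCTTGTTTCAGCTTGCTCGCATTTATGGAGCAATCTATCTTTTAGAGATTGAACTCTGAGCAAAGAATGGCTGATACGCAAGTAGTCCTAGTAGGCCACATGTCCGATTCTCTACCCTCCGGCTCATTTCAACACCACACTTACTTCCTGACCTGGTGTCCGCACAAATGACTTGCTTCGGGCTTGTATGTTAAACGGTTCCTAATGTACCTGAATCGCTTAATACGCTCTACTGAAACCGCGTTGCATAGACGACTCATTGGAAGAAACACATATGATCCTTATACAGACTGGGGTGATTTTTTGCCCGACTAATTATTAAATTGCAATCAGGAAATTTACGAAAGTGTACGACTGGATACAAACCCGGGCCCCGTAAGGAAAACAGGCCCAAGGGGTTGTATTCTTCACCTCATTACGATGATTGCTATCTTCATGTGTAAGACGAAACACGCTTGGCATGGACCGACTATTGATCTATTCGGCTAAGATTTCGCAATTGCTGATATACGTCGTTTTTTTCACGGACTGTAAACAAAAACCGTTGGCCTGGGATATTCTACCGAGCGTGAACATGCGGTAGCTTTTTAGGACCATGGGACGCTTACATTCGTATATGTTTCCATTTGACAGATAAAGTACATATAGATTCACCTAGACCTCCACCGATGTTAAATTACCTAGTGCGACCTGCTAGCCTAAACGCTGACGCCGTTTATGGAGGGATCCATTCCGAATCAGTACAAGCATTTACGTTATACCTGTAATGGTCTAGTAATTCTAGAGCACCGTCGGTACACAGAAGGTATATGAAAAAACATTGCGACCAGGGTGCGCGCTTCTTCCGCAGACAGATGAGGCTATCATAATTGTACATGTTATGAGAGTTCCCCGATATTGTTGTGGTTTTACAAACGCTTGATCTTTTATCTAGAAAACATGCACAAATTGTCGACAGCACCCCG
>synthetic_decoy_transcript
AGACTCTTTTTGCTATTTTCCAGTGAACGCACTCTGTCGATTGGCTAGGGTCCTACGGCTTCCCATCCGTGCCAGTTAATTAATTATGTCGTATTAAGGAAGCATGTTAAAAATTGAGGATAAGTAATTGCACAAACGTAGGGTTTCAGATCCTCTCGCTGCGTTATGAAAGGGAACGACAGGAGTCAAATCTAGACCCTCAGGAAAAATGTCACAAGTTAGTAGACCCCGAGGGCGAATAATTAATCAACAGTTGCCTGCATGAGAACCACCCCTAAAACAATAGTTAATCAAAAAAGTCGCTCTTGGACTGGCTAACTGTCCTTAAGCTGCCTGAAGGTGCGTAGGAGTTCAAAGGGAAAACGTTGCGCGGGTGTTAAGCCGCAAACTGTCATGTGTCTCGCTCAAAAAGAATCTGTTTCGGAATTTCAAGAGGGTACATCGTCTAATACTTGTTCTTAGGTAATACCCACTATACCCCTTATTGATTACCTCATGCATATAGAATTAGTGTTTATAACACGTAACGTGCGAAATCCTCGTGCCACGGCTATGTACACCCTACCATTGATAACATCTAGTCGGTAACAGCTTAGCATTGTCTCTGGAATAAAGCTACGTTTGTCGGGGCACCCTAAAAGTACCGTCTGTCTGTTCCCTGAAGAAAAAAACGTCACAAATAGTTTATCAATGTATTAGTGGTAGACATACGCAAGACTGTTGCTCTGCAGTTACGAACTCTGCGCTCGGGTAGTTTGAGAGTACTATCAAGAAAAGAATTCGCATCGGGTCATTATTCGCATAAAAGAGGTGAGACCTGACCACAGCCACTTAGTACAAACGACGACGAAACTCTGACGCGAGGGCAGGAATCCACACATAAGCGGGCCCCGAACGATAGCTCTAATTATATTTGCATAGCGTACAACTCAACCGACGAAGTACCAGAAGTTAGGCGACAAGTTGGCAGAAGCTATAGTGGCGTGACAAGCAATCATGA
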