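right_rbe	n_substitutions	cleavage_rate_pct
GATGTCAAGATAG	6	17.3
TGGAGCATGTCAT	6	23
CGTACAAAGTTAT	3	23.5
TCAACCAAGTTAT	3	26
TGCAACAAGTCAT	5	26.8
TCAACACATTTAT	5	28.3
GATACTTATTGAC	6	28.7
CATACCTCGTCAT	5	28.7
AAATCGAAGTCAT	4	29.4
AAAGCGGAGTTAT	4	29.5
AAAACGAAGTTAT	2	29.7
AAAACCAAGTTAT	3	29.8
TTCACCCAGTTTC	6	30.2
TCAACCAAGTAAT	4	30.4
CTGACGGAGTGAT	5	30.8
AAAACGATGTAAT	4	31.3
TCTACATAGATAT	4	31.5
TACATGACGCTAT	4	31.8
TACATCACCTTAT	5	31.9
TACATAAAGTCAT	4	31.9
TACACTGAGTTAG	4	32.2
CATCCCAAACTAT	5	32.2
GATAAGACGTTGT	4	32.3
GATTAGATGCTAC	6	32.4
TGTAGGCAGATAG	5	32.5
GATATGCAGTCAT	4	32.5
TACACAAATTCAT	4	32.5
GATAAAAAATTAC	5	32.6
CATATGACGTTAT	3	32.7
GATATCACGTTCT	5	32.9
GGTACGCACTTCT	5	33.2
CTTAGCCAGTTAT	5	33.4
TTCACGGGATTAT	5	33.4
GACACCAAGATAT	4	33.5
TACACGGAACTAG	5	33.5
TGTACTAAGTTCG	4	33.5
TCTACTATTTTAA	5	33.7
TGACCGACGTTAG	5	33.7
CATACCAAATTCT	4	33.8
TACACGTTATTCT	5	34
CTTACCAAGTTTT	4	34.1
TTTGTCACGTTAT	5	34.2
TTCTGGAAGTTAT	4	34.3
CGAGCGAACCTAT	6	34.4
CATTCAAAAGTAT	5	34.5
GATATGAAATTAT	3	34.5
CATATGTTGTCAA	6	34.5
TGTACGGAGTTCT	3	34.5
GATACCAAGTCAT	3	34.6
CATCGGAATTTAA	5	34.6
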