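exon_number	cdna_start	cdna_end
2	1	74
3	75	96
4	97	375
5	376	559
6	560	672
7	673	782
8	783	919
9	920	993
10	994	1100
11	1101	1182
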