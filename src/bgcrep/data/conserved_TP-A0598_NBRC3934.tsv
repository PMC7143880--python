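# Conservation map between TP-A0598 and NBRC 3934: the five clusters reported
# as present in both genomes (homology-based calls from the source study).
cluster_id_A	cluster_id_B	score
nrps-1	nrps-1	1.0
t1pks-1	t1pks-1	1.0
t1pks-2	t1pks-2	1.0
t2pks-1	t2pks-1	1.0
t3pks-1	t3pks-1	1.0
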