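"""Predict product backbones for the orphan clusters of the two reference strains.

Each NRPS / hybrid PKS-NRPS assembly line is walked module by module
(colinearity rule): annotated A-domain substrates print as residues
(Leu, Thr, ...), unannotated ones as 'x' (or 'mx' with a methyltransferase),
A-less C/T modules as 'y', and PKS extension modules as 'pk'.  A trailing
'-' marks a chain running off an incompletely sequenced cluster.
"""

from bgcrep import ClusterType, load_fixture, predict_backbone

for strain in ("TP-A0598", "NBRC3934"):
    inv = load_fixture(strain)
    print(f"\n{strain}:")
    for c in inv.clusters:
        if c.ctype not in (ClusterType.NRPS, ClusterType.PKS_NRPS):
            continue
        if c.known_product:
            print(f"  {c.cluster_id:12s} known product: {c.known_product}")
            continue
        print(f"  {c.cluster_id:12s} predicted backbone: {predict_backbone(c)}")
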