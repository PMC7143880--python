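"""Cluster typing and colinearity-rule backbone prediction."""

import pytest

from bgcrep import (
    ClusterType,
    GeneCluster,
    MissingExplicitOrder,
    Module,
    ModuleClass,
    NoSynthaseDomains,
    NotAnAssemblyLine,
    Orf,
    classify_cluster,
    classify_module,
    order_assembly_line,
    parse_domain_string,
    predict_backbone,
)
from bgcrep.backbone import auto_order_mode


def module(text: str) -> Module:
    (m,) = parse_domain_string(text)
    return m


def cluster(cid, ctype, *orf_texts, incomplete=()):
    orfs = [
        Orf(
            locus_tag=f"orf{i}",
            modules=tuple(parse_domain_string(t)),
            incomplete=(i in incomplete),
        )
        for i, t in enumerate(orf_texts)
    ]
    return GeneCluster(cluster_id=cid, ctype=ClusterType.parse(ctype), orfs=orfs)


@pytest.mark.parametrize(
    "text, expected",
    [
        ("C/A(val)/T", ModuleClass.NRPS_EXT),
        ("A(leu)/T", ModuleClass.NRPS_LOAD),
        ("A/MT/T", ModuleClass.NRPS_LOAD),
        ("C/T", ModuleClass.NRPS_NO_A),
        ("KS/AT/DH/ER/KR/ACP", ModuleClass.PKS_EXT),
        ("CoL/T", ModuleClass.PKS_LOAD),
        ("TE", ModuleClass.TERMINATION_ONLY),
        ("TD", ModuleClass.TERMINATION_ONLY),
        ("A", ModuleClass.FRAGMENT),
        ("ACP", ModuleClass.FRAGMENT),
        ("AT/KR/ACP", ModuleClass.FRAGMENT),
    ],
)
def test_classify_module(text, expected):
    assert classify_module(module(text)) is expected


def test_classify_cluster_types(tp_a0598, nbrc3934):
    assert classify_cluster(tp_a0598.cluster("t2pks-1")) is ClusterType.T2PKS
    assert classify_cluster(tp_a0598.cluster("t3pks-1")) is ClusterType.T3PKS
    assert classify_cluster(tp_a0598.cluster("pks/nrps-2")) is ClusterType.PKS_NRPS
    assert classify_cluster(tp_a0598.cluster("nrps-2")) is ClusterType.NRPS
    assert classify_cluster(nbrc3934.cluster("t1pks-4")) is ClusterType.T1PKS
    # every fixture cluster's declared type matches its derived type
    for inv in (tp_a0598, nbrc3934):
        for c in inv.clusters:
            assert classify_cluster(c) is c.ctype


def test_classify_cluster_no_synthase():
    with pytest.raises(NoSynthaseDomains):
        classify_cluster(cluster("x-1", "t1pks", "ACP", "KR"))


def test_order_file_order(tp_a0598):
    nrps1 = tp_a0598.cluster("nrps-1")
    assert [o.locus_tag for o in order_assembly_line(nrps1, "file_order")] == [
        "07_04820", "07_04810", "07_04800", "07_04790",
    ]


def test_order_explicit(tp_a0598):
    hybrid = tp_a0598.cluster("pks/nrps-2")
    assert [o.locus_tag for o in order_assembly_line(hybrid, "explicit")] == [
        "08_01890", "08_01960", "08_01950", "08_01940",
    ]
    with pytest.raises(MissingExplicitOrder):
        order_assembly_line(tp_a0598.cluster("nrps-1"), "explicit")


def test_order_heuristic_load_first_te_last():
    c = cluster("n", "nrps", "C/A/T-TE", "A(ser)/T", "C/A/T")
    assert [o.locus_tag for o in order_assembly_line(c, "heuristic")] == [
        "orf1", "orf2", "orf0",
    ]


def test_order_singleton_invariant_under_modes(tp_a0598):
    c = tp_a0598.cluster("t3pks-1")
    for mode in ("file_order", "heuristic"):
        assert order_assembly_line(c, mode) == c.orfs


GOLDEN = [
    ("TP-A0598", "nrps-1", "x-Leu-Val-y"),
    ("TP-A0598", "nrps-2", "x-Asp-Asn-Leu-Phe-Thr-y-Leu"),
    ("TP-A0598", "pks/nrps-2", "Ser-y-Val-pk"),
    ("NBRC3934", "nrps-3", "Leu-Ala-x-Ala-Leu-x-Thr-Orn-x-Leu"),
    ("NBRC3934", "nrps-4", "mx-x-Gly-"),
    ("NBRC3934", "nrps-5", "Thr-Thr-x, Arg-Pro"),
    ("NBRC3934", "pks/nrps-4", "Ala-Thr-pk"),
]


@pytest.mark.parametrize("strain, cid, expected", GOLDEN)
def test_golden_backbones(request, strain, cid, expected):
    inv = request.getfixturevalue(strain.lower().replace("-", "_"))
    assert str(predict_backbone(inv.cluster(cid))) == expected


def test_partial_chain_flag(nbrc3934):
    pred = predict_backbone(nbrc3934.cluster("nrps-4"))
    assert pred.chain_partial == [True]
    pred5 = predict_backbone(nbrc3934.cluster("nrps-5"))
    assert len(pred5.chains) == 2
    assert pred5.chain_partial == [False, False]  # both chains TE/TD-released


def test_t2pks_t3pks_rejected(tp_a0598):
    for cid in ("t2pks-1", "t3pks-1"):
        with pytest.raises(NotAnAssemblyLine):
            predict_backbone(tp_a0598.cluster(cid))


def test_epimerization_does_not_change_residues():
    plain = cluster("n", "nrps", "A(leu)/T-C/A(thr)/T-TE")
    with_e = cluster("n", "nrps", "A(leu)/T-C/A(thr)/T/E-TE")
    assert str(predict_backbone(plain)) == str(predict_backbone(with_e)) == "Leu-Thr"


def test_residue_count_matches_nrps_module_count(tp_a0598, nbrc3934):
    # pure NRPS clusters: one residue per LOAD/EXT/NO_A module walked
    for inv in (tp_a0598, nbrc3934):
        for c in inv.clusters:
            if c.ctype is not ClusterType.NRPS:
                continue
            n_mod = sum(
                classify_module(m)
                in (ModuleClass.NRPS_LOAD, ModuleClass.NRPS_EXT, ModuleClass.NRPS_NO_A)
                for m in c.modules
            )
            pred = predict_backbone(c)
            assert sum(len(ch) for ch in pred.chains) == n_mod


def test_prediction_deterministic(tp_a0598):
    a = [str(predict_backbone(c)) for c in tp_a0598.clusters if c.ctype
         in (ClusterType.NRPS, ClusterType.PKS_NRPS)]
    b = [str(predict_backbone(c)) for c in tp_a0598.clusters if c.ctype
         in (ClusterType.NRPS, ClusterType.PKS_NRPS)]
    assert a == b


def test_auto_mode_uses_explicit_when_present(tp_a0598):
    assert auto_order_mode(tp_a0598.cluster("pks/nrps-2")) == "explicit"
    assert auto_order_mode(tp_a0598.cluster("nrps-1")) == "file_order"
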