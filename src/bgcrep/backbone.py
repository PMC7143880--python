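"""Cluster typing and colinearity-rule backbone prediction.

Type I PKS and NRPS assembly lines obey the colinearity rule: the order
of building blocks in the product mirrors the order of modules along the
enzymes.  Walking the modules of a cluster in assembly order therefore
yields a backbone string, with one token per chain-extending module:

* an NRPS module whose A domain has a substrate call emits that residue
  (``Leu``, ``Thr``, ...);
* an NRPS module with an A domain but no substrate call emits ``x``
  (unidentified amino acid);
* an NRPS module carrying an MT domain emits ``mx`` (methyl-amino acid)
  when the substrate itself is unknown;
* a module with C and T but no A domain emits ``y`` (unknown building
  block supplied in trans or left uncharged);
* a PKS extension module emits ``pk`` (polyketide-derived moiety).

Thioesterase (TE) and terminal-reductase (TD) domains release the chain;
residues emitted after a release start a new chain.  Epimerization (E)
domains do not change the emitted residue.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .model import (
    ClusterType,
    DomainKind,
    GeneCluster,
    MissingExplicitOrder,
    Module,
    ModuleClass,
    NoSynthaseDomains,
    NotAnAssemblyLine,
    Orf,
)

_PKS_KINDS = {DomainKind.KS, DomainKind.KSALPHA, DomainKind.KSBETA_CLF}
_RELEASE = {DomainKind.TE, DomainKind.TD}


class ResidueKind(str, enum.Enum):
    AA = "AA"
    X = "X"
    Y = "Y"
    MX = "MX"
    PK = "PK"


@dataclass(frozen=True)
class ResidueToken:
    """One building block of a predicted backbone."""

    kind: ResidueKind
    residue: str | None = None  # capitalized code, present iff kind is AA

    def __str__(self) -> str:
        if self.kind is ResidueKind.AA:
            return self.residue or "?"
        return {"X": "x", "Y": "y", "MX": "mx", "PK": "pk"}[self.kind.value]


@dataclass
class BackbonePrediction:
    """Predicted backbone: one or more chains of residue tokens.

    ``chain_partial[i]`` is True for an open-ended chain (the assembly
    line runs off the end of an incompletely sequenced cluster); such
    chains serialize with a trailing ``-``.
    """

    cluster_id: str
    chains: list[list[ResidueToken]]
    chain_partial: list[bool]

    def __str__(self) -> str:
        parts = []
        for chain, partial in zip(self.chains, self.chain_partial):
            s = "-".join(str(t) for t in chain)
            if partial:
                s += "-"
            parts.append(s)
        return ", ".join(parts)


def classify_module(m: Module) -> ModuleClass:
    """Classify one module by its domain content.

    Pure function of the domain set; ``FRAGMENT`` is the fallback for
    stray single domains (a lone A, ACP or AT).
    """
    kinds = set(m.kinds)
    if kinds & _PKS_KINDS:
        return ModuleClass.PKS_EXT
    if DomainKind.COL in kinds:
        return ModuleClass.PKS_LOAD
    if DomainKind.A in kinds and DomainKind.T in kinds:
        return ModuleClass.NRPS_EXT if DomainKind.C in kinds else ModuleClass.NRPS_LOAD
    if DomainKind.C in kinds and DomainKind.T in kinds:
        return ModuleClass.NRPS_NO_A
    if kinds and kinds <= _RELEASE:
        return ModuleClass.TERMINATION_ONLY
    return ModuleClass.FRAGMENT


_NRPS_CLASSES = {ModuleClass.NRPS_EXT, ModuleClass.NRPS_LOAD, ModuleClass.NRPS_NO_A}
_PKS_CLASSES = {ModuleClass.PKS_EXT, ModuleClass.PKS_LOAD}


def classify_cluster(c: GeneCluster) -> ClusterType:
    """Derive the cluster type from domain content.

    Type II PKS: dissociated KSalpha + KSbeta(CLF) subunits.  Type III
    PKS: a single standalone-KS ORF and nothing else.  Hybrid: both PKS
    and NRPS modules present.  Otherwise NRPS or (multidomain KS/AT
    ORFs) type I PKS.
    """
    if not c.orfs:
        raise NoSynthaseDomains(f"cluster {c.cluster_id} has no ORFs")
    all_kinds = {k for o in c.orfs for m in o.modules for k in m.kinds}
    if DomainKind.KSALPHA in all_kinds and DomainKind.KSBETA_CLF in all_kinds:
        return ClusterType.T2PKS
    if (
        len(c.orfs) == 1
        and len(c.orfs[0].modules) == 1
        and c.orfs[0].modules[0].kinds == (DomainKind.KS,)
    ):
        return ClusterType.T3PKS
    classes = {classify_module(m) for o in c.orfs for m in o.modules}
    has_pks = bool(classes & _PKS_CLASSES)
    has_nrps = bool(classes & _NRPS_CLASSES)
    if has_pks and has_nrps:
        return ClusterType.PKS_NRPS
    if has_nrps:
        return ClusterType.NRPS
    if has_pks:
        return ClusterType.T1PKS
    if not all_kinds & {DomainKind.KS, DomainKind.C, DomainKind.A, DomainKind.T}:
        raise NoSynthaseDomains(
            f"cluster {c.cluster_id} contains no KS/C/A/T domain"
        )
    return ClusterType.T1PKS


def order_assembly_line(c: GeneCluster, mode: str = "file_order") -> list[Orf]:
    """Return ORFs in the order the assembly line is walked.

    ``file_order`` keeps the listed order (published tables are already
    in assembly order for all but a couple of clusters); ``explicit``
    follows the cluster's recorded ``assembly_order``; ``heuristic``
    moves the ORF starting with a LOAD-class module to the front and a
    TE/TD-terminated ORF to the back, otherwise preserving file order.
    """
    if mode == "file_order":
        return list(c.orfs)
    if mode == "explicit":
        if not c.assembly_order:
            raise MissingExplicitOrder(
                f"cluster {c.cluster_id} has no explicit assembly_order"
            )
        return [c.orf(tag) for tag in c.assembly_order]
    if mode == "heuristic":
        if len(c.orfs) <= 1:
            return list(c.orfs)
        orfs = list(c.orfs)

        def rank(o: Orf) -> int:
            first = classify_module(o.modules[0])
            last_kinds = set(o.modules[-1].kinds)
            if first in (ModuleClass.NRPS_LOAD, ModuleClass.PKS_LOAD):
                return 0
            if last_kinds & _RELEASE:
                return 2
            return 1

        return sorted(orfs, key=rank)  # stable: file order within ranks
    raise ValueError(f"unknown ordering mode {mode!r}")


def auto_order_mode(c: GeneCluster) -> str:
    """``explicit`` when the cluster records an assembly order, else file order."""
    return "explicit" if c.assembly_order else "file_order"


def _emit(m: Module, cls: ModuleClass) -> ResidueToken | None:
    if cls in (ModuleClass.NRPS_EXT, ModuleClass.NRPS_LOAD):
        sub = m.substrate
        if sub is not None:
            return ResidueToken(ResidueKind.AA, sub.capitalize())
        if m.has(DomainKind.MT):
            return ResidueToken(ResidueKind.MX)
        return ResidueToken(ResidueKind.X)
    if cls is ModuleClass.NRPS_NO_A:
        return ResidueToken(ResidueKind.Y)
    if cls is ModuleClass.PKS_EXT:
        return ResidueToken(ResidueKind.PK)
    if cls is ModuleClass.FRAGMENT:
        # a lone A domain with a substrate call acts in trans and still
        # contributes its residue to the chain
        if len(m.domains) == 1 and m.domains[0].kind is DomainKind.A and m.substrate:
            return ResidueToken(ResidueKind.AA, m.substrate.capitalize())
    return None  # PKS_LOAD, TERMINATION_ONLY, silent fragments


def predict_backbone(c: GeneCluster, mode: str = "auto") -> BackbonePrediction:
    """Predict the product backbone of an assembly-line cluster.

    ``mode`` selects the ORF walk order (see :func:`order_assembly_line`);
    ``auto`` uses the cluster's explicit order when recorded, else file
    order.  Type II/III PKS clusters are not assembly lines and are
    rejected.
    """
    ctype = classify_cluster(c)
    if ctype in (ClusterType.T2PKS, ClusterType.T3PKS):
        raise NotAnAssemblyLine(
            f"cluster {c.cluster_id} is {ctype.value}; no colinear assembly line"
        )
    if mode == "auto":
        mode = auto_order_mode(c)
    orfs = order_assembly_line(c, mode)

    chains: list[list[ResidueToken]] = []
    chain_partial: list[bool] = []
    current: list[ResidueToken] = []
    for orf in orfs:
        for m in orf.modules:
            tok = _emit(m, classify_module(m))
            if tok is not None:
                current.append(tok)
            if set(m.kinds) & _RELEASE:
                if current:
                    chains.append(current)
                    chain_partial.append(False)
                    current = []
    if current:
        open_ended = c.partial or any(o.incomplete for o in orfs)
        chains.append(current)
        chain_partial.append(open_ended)
    return BackbonePrediction(c.cluster_id, chains, chain_partial)
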