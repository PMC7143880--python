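"""Core data model for PKS/NRPS gene-cluster inventories.

A strain's secondary-metabolite potential is represented as a
:class:`StrainInventory`: a set of biosynthetic gene clusters
(:class:`GeneCluster`), each a list of open reading frames
(:class:`Orf`) whose catalytic domain organization is recorded as
ordered :class:`Module` objects built from :class:`DomainToken`.

The domain vocabulary covers the canonical type-I PKS domains
(KS, AT, DH, ER, KR, ACP), the dissociated type-II PKS subunits
(KSalpha, KSbeta_CLF), NRPS domains (C, A, T, E, MT), chain-release
domains (TE, TD), a CoA-ligase loading domain (CoL), the
dihydroxybenzoate starter abbreviation (DHB) and a GAP marker for
stretches of undetermined domains.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class BgcrepError(Exception):
    """Base class for all package errors."""


class UnknownDomainToken(BgcrepError):
    """A domain-organization string contains an unrecognized code."""


class EmptyModule(BgcrepError):
    """Consecutive module separators (or an empty token) in a domain string."""


class FormatError(BgcrepError):
    """An inventory file is malformed (carries the offending row/line)."""


class DuplicateClusterId(FormatError):
    """Two clusters in one strain share an id."""


class NoSynthaseDomains(BgcrepError):
    """A cluster contains none of KS/C/A/T and cannot be typed."""


class NotAnAssemblyLine(BgcrepError):
    """Backbone prediction requested for a type II/III PKS cluster."""


class MissingExplicitOrder(BgcrepError):
    """mode='explicit' requested but the cluster has no assembly_order."""


class UnknownClusterId(BgcrepError):
    """A conservation map references a cluster id absent from the inventories."""


class InsufficientData(BgcrepError):
    """Too few complete-case records for a regression."""


class ConfigError(BgcrepError):
    """Invalid synthetic-generator configuration."""


class EmptySequence(BgcrepError):
    """An empty nucleotide sequence was supplied."""


class LengthMismatch(BgcrepError):
    """Pre-aligned sequences differ in length."""


class DomainKind(str, enum.Enum):
    """Closed enumeration of catalytic domain codes."""

    KS = "KS"
    AT = "AT"
    DH = "DH"
    ER = "ER"
    KR = "KR"
    ACP = "ACP"
    C = "C"
    A = "A"
    T = "T"
    E = "E"
    MT = "MT"
    TE = "TE"
    TD = "TD"
    COL = "CoL"
    KSALPHA = "KSalpha"
    KSBETA_CLF = "KSbeta_CLF"
    DHB = "DHB"
    GAP = "GAP"


class ModuleClass(str, enum.Enum):
    """Functional class of one module of an assembly line."""

    NRPS_EXT = "NRPS_EXT"
    NRPS_LOAD = "NRPS_LOAD"
    NRPS_NO_A = "NRPS_NO_A"
    PKS_EXT = "PKS_EXT"
    PKS_LOAD = "PKS_LOAD"
    TERMINATION_ONLY = "TERMINATION_ONLY"
    FRAGMENT = "FRAGMENT"


class ClusterType(str, enum.Enum):
    """Biosynthetic cluster type."""

    T1PKS = "t1pks"
    T2PKS = "t2pks"
    T3PKS = "t3pks"
    NRPS = "nrps"
    PKS_NRPS = "pks/nrps"

    @classmethod
    def parse(cls, text: str) -> "ClusterType":
        t = text.strip().lower().replace("_", "/").replace("-", "/")
        for member in cls:
            if member.value == t or member.value.replace("/", "") == t.replace("/", ""):
                return member
        raise FormatError(f"unknown cluster type: {text!r}")


@dataclass(frozen=True)
class DomainToken:
    """One catalytic domain, optionally with an annotated substrate.

    Substrates are the lowercase residue codes of adenylation-domain
    specificity calls (e.g. ``leu``); they occur on A tokens and, rarely,
    on the T token of a module whose A domain sits elsewhere.
    """

    kind: DomainKind
    substrate: str | None = None

    def __post_init__(self) -> None:
        if self.substrate is not None and self.kind not in (DomainKind.A, DomainKind.T):
            raise UnknownDomainToken(
                f"substrate {self.substrate!r} not allowed on {self.kind.value}"
            )


@dataclass(frozen=True)
class Module:
    """A hyphen-delimited segment of a domain-organization string."""

    domains: tuple[DomainToken, ...]

    @property
    def kinds(self) -> tuple[DomainKind, ...]:
        return tuple(d.kind for d in self.domains)

    @property
    def substrate(self) -> str | None:
        """The module's substrate call: from its A token, else its T token."""
        for want in (DomainKind.A, DomainKind.T):
            for d in self.domains:
                if d.kind is want and d.substrate is not None:
                    return d.substrate
        return None

    def has(self, kind: DomainKind) -> bool:
        return any(d.kind is kind for d in self.domains)


@dataclass
class Orf:
    """One open reading frame of a cluster.

    ``size_aa`` is descriptive metadata (amino-acid length);
    ``size_is_lower_bound`` records a ``>`` prefix in the source table and
    ``incomplete`` marks ORFs truncated at a scaffold terminus.
    """

    locus_tag: str
    modules: tuple[Module, ...]
    size_aa: int | None = None
    size_is_lower_bound: bool = False
    incomplete: bool = False


@dataclass
class GeneCluster:
    """One biosynthetic gene cluster of a strain."""

    cluster_id: str
    ctype: ClusterType
    orfs: list[Orf] = field(default_factory=list)
    known_product: str | None = None
    partial: bool = False
    assembly_order: list[str] | None = None

    def orf(self, locus_tag: str) -> Orf:
        for o in self.orfs:
            if o.locus_tag == locus_tag:
                return o
        raise KeyError(locus_tag)

    @property
    def modules(self) -> list[Module]:
        """All modules, ORFs in listed order."""
        return [m for o in self.orfs for m in o.modules]


@dataclass
class StrainInventory:
    """A strain's full PKS/NRPS cluster repertoire."""

    strain_id: str
    clusters: list[GeneCluster] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.strain_id:
            raise FormatError("strain_id must be non-empty")
        seen: set[str] = set()
        for c in self.clusters:
            if c.cluster_id in seen:
                raise DuplicateClusterId(
                    f"duplicate cluster id {c.cluster_id!r} in strain {self.strain_id}"
                )
            seen.add(c.cluster_id)

    def cluster(self, cluster_id: str) -> GeneCluster:
        for c in self.clusters:
            if c.cluster_id == cluster_id:
                return c
        raise UnknownClusterId(cluster_id)

    @property
    def cluster_ids(self) -> list[str]:
        return [c.cluster_id for c in self.clusters]

    def __len__(self) -> int:
        return len(self.clusters)


__all__ = [name for name in dir() if not name.startswith("_")]
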