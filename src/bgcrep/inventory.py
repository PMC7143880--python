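"""Reading, writing and parsing of cluster inventories.

The domain-organization grammar mirrors how published cluster tables
print module architecture: domains within a module are joined by ``/``,
modules within an ORF by ``-``, and A-domain substrate calls appear as a
parenthesized lowercase code, e.g. ``C/A(leu)/T``.  The Markdown-escaped
dialect ``A_(leu)_`` is accepted on input; the type-II PKS subunits may
be written ``KSa``/``KSα``/``KSalpha`` and ``KSb(CLF)``/``KSβ (CLF)``.
``...`` (or the ellipsis character) marks a stretch of undetermined
domains.

Inventory files are TSV (or an equivalent JSON mirror) with one row per
ORF and cluster-level fields repeated::

    strain_id  cluster_id  ctype  known_product  locus_tag  size_aa
    domain_organization  incomplete  assembly_order

``#``-prefixed lines are comments.  ``size_aa`` may carry a ``>`` prefix
(lower bound) and a thousands separator; ``assembly_order`` is a
``|``-separated locus-tag list given on a cluster's first row when the
biological assembly-line order differs from row order.
"""

from __future__ import annotations

import csv
import json
import re
import warnings
from importlib import resources
from pathlib import Path

from .model import (
    ClusterType,
    DomainKind,
    DomainToken,
    DuplicateClusterId,
    EmptyModule,
    FormatError,
    GeneCluster,
    Module,
    Orf,
    StrainInventory,
    UnknownDomainToken,
)

_PLAIN_CODES = {
    "KS": DomainKind.KS,
    "AT": DomainKind.AT,
    "DH": DomainKind.DH,
    "ER": DomainKind.ER,
    "KR": DomainKind.KR,
    "ACP": DomainKind.ACP,
    "C": DomainKind.C,
    "A": DomainKind.A,
    "T": DomainKind.T,
    "E": DomainKind.E,
    "MT": DomainKind.MT,
    "TE": DomainKind.TE,
    "TD": DomainKind.TD,
    "CoL": DomainKind.COL,
    "DHB": DomainKind.DHB,
    "KSa": DomainKind.KSALPHA,
    "KSalpha": DomainKind.KSALPHA,
    "KSb": DomainKind.KSBETA_CLF,
    "KSb(CLF)": DomainKind.KSBETA_CLF,
    "KSbeta": DomainKind.KSBETA_CLF,
    "KSbeta(CLF)": DomainKind.KSBETA_CLF,
    "KSbeta_CLF": DomainKind.KSBETA_CLF,
    "...": DomainKind.GAP,
}

# canonical serialization per domain kind
_CANONICAL = {
    DomainKind.KSALPHA: "KSa",
    DomainKind.KSBETA_CLF: "KSb(CLF)",
    DomainKind.GAP: "...",
}

_SUBSTRATE_RE = re.compile(r"^(?P<code>[A-Za-z]+)\((?P<sub>[a-z]{2,5})\)$")

TSV_COLUMNS = [
    "strain_id",
    "cluster_id",
    "ctype",
    "known_product",
    "locus_tag",
    "size_aa",
    "domain_organization",
    "incomplete",
    "assembly_order",
]


def _normalize(text: str) -> str:
    t = text.strip()
    t = t.replace("…", "...")  # ellipsis character
    t = t.replace("α", "a").replace("β", "b")  # Greek alpha/beta
    t = t.replace("_(", "(").replace(")_", ")")  # Markdown-escaped subscripts
    t = re.sub(r"\s+\(", "(", t)  # "KSb (CLF)" -> "KSb(CLF)"
    return t


def parse_domain_token(text: str) -> DomainToken:
    """Parse one domain token, e.g. ``A(leu)``, ``KSb(CLF)`` or ``KR``."""
    t = _normalize(text)
    if not t:
        raise EmptyModule("empty domain token")
    m = _SUBSTRATE_RE.match(t)
    if m:
        code, sub = m.group("code"), m.group("sub")
        kind = _PLAIN_CODES.get(code)
        if kind is None:
            raise UnknownDomainToken(f"unknown domain code {code!r} in token {text!r}")
        if kind not in (DomainKind.A, DomainKind.T):
            raise UnknownDomainToken(
                f"substrate subscript on non-A/T domain in token {text!r}"
            )
        return DomainToken(kind, sub)
    kind = _PLAIN_CODES.get(t)
    if kind is None:
        raise UnknownDomainToken(f"unknown domain token {text!r}")
    return DomainToken(kind)


def parse_domain_string(text: str) -> list[Module]:
    """Parse a full domain-organization string into ordered modules.

    >>> [m.kinds for m in parse_domain_string("C/A(leu)/T")]
    [(<DomainKind.C: 'C'>, <DomainKind.A: 'A'>, <DomainKind.T: 'T'>)]
    """
    t = _normalize(text)
    if not t:
        raise EmptyModule("empty domain-organization string")
    modules: list[Module] = []
    for mod_text in t.split("-"):
        if not mod_text.strip():
            raise EmptyModule(f"empty module (consecutive hyphens) in {text!r}")
        tokens = tuple(parse_domain_token(tok) for tok in mod_text.split("/"))
        modules.append(Module(tokens))
    return modules


def serialize_token(tok: DomainToken) -> str:
    base = _CANONICAL.get(tok.kind, tok.kind.value)
    if tok.substrate is not None:
        return f"{base}({tok.substrate})"
    return base


def serialize_modules(modules: list[Module] | tuple[Module, ...]) -> str:
    """Canonical domain-organization string (``A(leu)`` dialect)."""
    return "-".join("/".join(serialize_token(t) for t in m.domains) for m in modules)


def _parse_size(text: str) -> tuple[int | None, bool]:
    t = text.strip().replace(",", "")
    if not t:
        return None, False
    lower = t.startswith(">")
    if lower:
        t = t[1:]
    try:
        return int(t), lower
    except ValueError as exc:
        raise FormatError(f"bad size_aa value {text!r}") from exc


def _format_size(orf: Orf) -> str:
    if orf.size_aa is None:
        return ""
    return f">{orf.size_aa}" if orf.size_is_lower_bound else str(orf.size_aa)


def _build_inventory(strain_id: str, rows: list[dict]) -> StrainInventory:
    clusters: list[GeneCluster] = []
    by_id: dict[str, GeneCluster] = {}
    open_cid: str | None = None
    for row in rows:
        cid = row["cluster_id"]
        if cid != open_cid:
            if cid in by_id:
                raise DuplicateClusterId(
                    f"cluster {cid!r} listed in non-contiguous blocks"
                )
            open_cid = cid
            cluster = GeneCluster(
                cluster_id=cid,
                ctype=ClusterType.parse(row["ctype"]),
                known_product=row.get("known_product") or None,
                assembly_order=(
                    row["assembly_order"].split("|") if row.get("assembly_order") else None
                ),
            )
            by_id[cid] = cluster
            clusters.append(cluster)
        cluster = by_id[cid]
        size_aa, lower = _parse_size(row.get("size_aa", ""))
        tag = row["locus_tag"].strip()
        if not tag:
            raise FormatError(f"empty locus_tag in cluster {cid!r}")
        if any(o.locus_tag == tag for o in cluster.orfs):
            raise FormatError(f"duplicate locus_tag {tag!r} in cluster {cid!r}")
        cluster.orfs.append(
            Orf(
                locus_tag=tag,
                modules=tuple(parse_domain_string(row["domain_organization"])),
                size_aa=size_aa,
                size_is_lower_bound=lower,
                incomplete=str(row.get("incomplete", "")).strip() in ("1", "true", "True"),
            )
        )
    for cluster in clusters:
        product = (cluster.known_product or "").lower()
        cluster.partial = any(o.incomplete for o in cluster.orfs) or product.endswith(
            ", partial"
        )
    inv = StrainInventory(strain_id=strain_id, clusters=clusters)
    _check_types(inv)
    return inv


def _check_types(inv: StrainInventory) -> None:
    # declared ctype vs domain content: warn, never fail
    from .backbone import classify_cluster

    for c in inv.clusters:
        try:
            derived = classify_cluster(c)
        except Exception:
            continue
        if derived is not c.ctype:
            warnings.warn(
                f"cluster {c.cluster_id} of {inv.strain_id}: declared type "
                f"{c.ctype.value} but domain content implies {derived.value}",
                stacklevel=3,
            )


def read_inventory(path: str | Path, format: str | None = None) -> StrainInventory:
    """Read a strain inventory from a TSV or JSON file."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "tsv")
    if fmt == "json":
        data = json.loads(path.read_text())
        rows = []
        for c in data["clusters"]:
            for o in c["orfs"]:
                rows.append(
                    {
                        "cluster_id": c["cluster_id"],
                        "ctype": c["ctype"],
                        "known_product": c.get("known_product") or "",
                        "locus_tag": o["locus_tag"],
                        "size_aa": (
                            (">" if o.get("size_is_lower_bound") else "")
                            + str(o.get("size_aa") or "")
                            if o.get("size_aa") is not None
                            else ""
                        ),
                        "domain_organization": o["domain_organization"],
                        "incomplete": "1" if o.get("incomplete") else "",
                        "assembly_order": "|".join(c.get("assembly_order") or []),
                    }
                )
        return _build_inventory(data["strain_id"], rows)
    if fmt != "tsv":
        raise FormatError(f"unknown inventory format {fmt!r}")
    rows = []
    strain_id = None
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    missing = {"strain_id", "cluster_id", "ctype", "locus_tag", "domain_organization"} - set(
        reader.fieldnames or []
    )
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    for i, row in enumerate(reader, start=2):
        try:
            if strain_id is None:
                strain_id = row["strain_id"].strip()
            elif row["strain_id"].strip() != strain_id:
                raise FormatError("multiple strain_id values in one inventory file")
            rows.append(row)
        except (UnknownDomainToken, EmptyModule, FormatError) as exc:
            raise FormatError(f"{path}, data row {i}: {exc}") from exc
    if strain_id is None:
        raise FormatError(f"{path}: no data rows")
    try:
        return _build_inventory(strain_id, rows)
    except (UnknownDomainToken, EmptyModule) as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_inventory(inv: StrainInventory, path: str | Path, format: str | None = None) -> None:
    """Write an inventory in canonical form; round-trips through read_inventory."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "tsv")
    if fmt == "json":
        doc = {
            "strain_id": inv.strain_id,
            "clusters": [
                {
                    "cluster_id": c.cluster_id,
                    "ctype": c.ctype.value,
                    "known_product": c.known_product,
                    "assembly_order": c.assembly_order,
                    "orfs": [
                        {
                            "locus_tag": o.locus_tag,
                            "size_aa": o.size_aa,
                            "size_is_lower_bound": o.size_is_lower_bound,
                            "incomplete": o.incomplete,
                            "domain_organization": serialize_modules(o.modules),
                        }
                        for o in c.orfs
                    ],
                }
                for c in inv.clusters
            ],
        }
        path.write_text(json.dumps(doc, indent=1) + "\n")
        return
    if fmt != "tsv":
        raise FormatError(f"unknown inventory format {fmt!r}")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for c in inv.clusters:
            for j, o in enumerate(c.orfs):
                writer.writerow(
                    [
                        inv.strain_id,
                        c.cluster_id,
                        c.ctype.value,
                        c.known_product or "",
                        o.locus_tag,
                        _format_size(o),
                        serialize_modules(o.modules),
                        "1" if o.incomplete else "",
                        "|".join(c.assembly_order) if j == 0 and c.assembly_order else "",
                    ]
                )


def load_fixture(name: str) -> StrainInventory:
    """Load a packaged inventory fixture by strain name.

    Packaged fixtures: ``TP-A0598`` (*Streptomyces lydicamycinicus*) and
    ``NBRC3934`` (*S. angustmyceticus*), transcribed from the published
    cluster tables of the two strains.
    """
    ref = resources.files("bgcrep.data").joinpath(f"{name}.tsv")
    with resources.as_file(ref) as p:
        if not p.exists():
            raise FileNotFoundError(f"no packaged fixture named {name!r}")
        return read_inventory(p)
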