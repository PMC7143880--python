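"""Concordance of cluster-repertoire conservation with genome relatedness.

Each strain pair is one record carrying up to four percentages: 16S
rDNA similarity, digital DNA–DNA hybridization (dDDH), average
nucleotide identity (ANI) and the conserved-cluster rate RC.  Strain
pairs are called the same genomic species when dDDH ≥ 70% (with
ANI ≥ 95% as the fallback criterion when no dDDH value is available).
Ordinary least squares over the complete-case records quantifies how
well one relatedness measure tracks another — in particular whether RC
is proportional to dDDH across phylogenetically close strain pairs.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

from scipy import stats

from .model import InsufficientData

DDH_SPECIES_CUTOFF = 70.0
ANI_SPECIES_CUTOFF = 95.0


@dataclass
class PairRecord:
    """One strain pair's relatedness measurements (percent, or None)."""

    pair_id: str
    sim16s: float | None = None
    ddh: float | None = None
    ani: float | None = None
    rc: float | None = None

    def __post_init__(self) -> None:
        for name in ("sim16s", "ddh", "ani", "rc"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100] for {self.pair_id}")


@dataclass(frozen=True)
class RegressionSummary:
    """OLS fit of y on x over complete-case records."""

    n: int
    slope: float
    intercept: float
    r: float

    @property
    def r_squared(self) -> float:
        return self.r * self.r


def classify_species(
    rec: PairRecord,
    ddh_cutoff: float = DDH_SPECIES_CUTOFF,
    ani_cutoff: float = ANI_SPECIES_CUTOFF,
) -> str:
    """Call a pair 'same' / 'different' species, or 'undetermined'.

    dDDH is authoritative when present (same species iff dDDH ≥ cutoff,
    boundary inclusive); otherwise ANI decides; with neither measure the
    call is undetermined.
    """
    if rec.ddh is not None:
        return "same" if rec.ddh >= ddh_cutoff else "different"
    if rec.ani is not None:
        return "same" if rec.ani >= ani_cutoff else "different"
    return "undetermined"


_FIELDS = {"sim16s": "sim16s", "ddh": "ddh", "ani": "ani", "rc": "rc"}


def _value(rec: PairRecord, var: str) -> float | None:
    key = var.strip().lower().replace("16s", "16s")
    aliases = {
        "sim16s": "sim16s",
        "16s": "sim16s",
        "ddh": "ddh",
        "dddh": "ddh",
        "ani": "ani",
        "rc": "rc",
    }
    if key not in aliases:
        raise KeyError(f"unknown variable {var!r}")
    return getattr(rec, aliases[key])


def regress(records: list[PairRecord], xvar: str, yvar: str) -> RegressionSummary:
    """Least-squares fit of ``yvar`` on ``xvar`` over complete cases.

    Records missing either variable are excluded; at least three
    complete cases are required.
    """
    xs, ys = [], []
    for rec in records:
        x, y = _value(rec, xvar), _value(rec, yvar)
        if x is not None and y is not None:
            xs.append(x)
            ys.append(y)
    if len(xs) < 3:
        raise InsufficientData(
            f"need >= 3 complete-case records for {yvar} ~ {xvar}, have {len(xs)}"
        )
    fit = stats.linregress(xs, ys)
    r = 0.0 if math.isnan(fit.rvalue) else float(fit.rvalue)
    slope = 0.0 if math.isnan(fit.slope) else float(fit.slope)
    return RegressionSummary(n=len(xs), slope=slope, intercept=float(fit.intercept), r=r)


def read_pair_table(path: str | Path) -> list[PairRecord]:
    """Read a strain-pair TSV (pair_id, sim16S, dDDH, ANI, RC)."""
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    colmap = {}
    for col in reader.fieldnames or []:
        key = col.strip().lower()
        if key in ("sim16s", "16s", "sim_16s"):
            colmap[col] = "sim16s"
        elif key in ("dddh", "ddh"):
            colmap[col] = "ddh"
        elif key == "ani":
            colmap[col] = "ani"
        elif key == "rc":
            colmap[col] = "rc"
    records = []
    for row in reader:
        kwargs: dict = {"pair_id": row["pair_id"]}
        for col, attr in colmap.items():
            text = (row.get(col) or "").strip()
            if text:
                kwargs[attr] = float(text)
        records.append(PairRecord(**kwargs))
    return records


def write_pair_table(records: list[PairRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["pair_id", "sim16S", "dDDH", "ANI", "RC"])
        for rec in records:
            writer.writerow(
                [rec.pair_id]
                + ["" if v is None else f"{v:g}" for v in (rec.sim16s, rec.ddh, rec.ani, rec.rc)]
            )
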