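"""PDBbind-style index parsing, quality criteria, tiers and blind splits.

An index file is a whitespace-column text file, one complex per line::

    # comment / header lines start with '#'
    3zzf  2.20  2012  0.40  Ki=400mM       // anything after // is comment
    1abc  NMR   1999  5.00  Kd~10uM  flags=covalent

Columns: PDB code, resolution in Angstrom (or ``NMR``), deposition year,
p-affinity (-log10 of molar Kd/Ki/IC50), and the affinity string whose
qualifier decides exactness ('=' exact; '~', '<', '>', '<=', '>=' approximate).
An optional ``flags=a,b`` token carries quality-defect annotations that cannot
be derived from the line itself (covalency, completeness, ...); for real data
these come from upstream curation (optionally via a sidecar CSV), for
synthetic fixtures from the generator.

The refined-quality predicate and the tier constructors implement the usual
high-quality criteria: crystal structure at resolution <= 2.5 A, exact Kd or
Ki measurement, and none of the structural defect flags.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "IndexRecord",
    "TierSpec",
    "IndexParseError",
    "DEFECT_FLAGS",
    "parse_index",
    "load_annotations",
    "apply_general_filters",
    "is_refined_quality",
    "make_tier",
    "blind_split",
    "subtract_codes",
]

#: recognised quality-defect flag codes
DEFECT_FLAGS = frozenset(
    {
        "non_protein_ligand",
        "conversion_failed",
        "nmr",
        "covalent",
        "uncommon_element",
        "peptide_ge10",
        "nucleotide_ge4",
        "incomplete",
        "multi_ligand",
    }
)

#: defect flags that disqualify a complex from refined quality (beyond
#: resolution, NMR and the Kd/Ki-exact requirements, which are field-level)
_STRUCTURAL_DEFECTS = frozenset(
    {
        "covalent",
        "uncommon_element",
        "peptide_ge10",
        "nucleotide_ge4",
        "incomplete",
        "multi_ligand",
        "non_protein_ligand",
    }
)

_KNOWN_UNITS = {"fM", "pM", "nM", "uM", "mM", "M"}
_AFFINITY_RE = re.compile(
    r"^(Kd|Ki|IC50)\s*(=|~|<=|>=|<|>|≤|≥)\s*([0-9.eE+-]+)\s*([a-zA-Z]+)$"
)


class IndexParseError(ValueError):
    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        loc = "" if line_no is None else f"line {line_no}: "
        super().__init__(loc + message)


@dataclass
class IndexRecord:
    """One index entry with its quality annotations."""

    pdb_code: str
    resolution: float | None  # None <=> NMR structure
    year: int
    p_affinity: float
    measure_kind: str  # Kd | Ki | IC50
    exact: bool
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.pdb_code = self.pdb_code.lower()
        if self.resolution is None:
            self.flags.add("nmr")
        elif self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if "nmr" in self.flags and self.resolution is not None:
            raise ValueError("nmr flag requires an NMR resolution marker")
        unknown = self.flags - DEFECT_FLAGS
        if unknown:
            raise ValueError(f"unknown defect flags: {sorted(unknown)}")


def _parse_affinity(token: str, line_no: int) -> tuple[str, bool]:
    m = _AFFINITY_RE.match(token)
    if not m:
        raise IndexParseError(f"malformed affinity string {token!r}", line_no)
    kind, qualifier, _value, unit = m.groups()
    if unit not in _KNOWN_UNITS:
        raise IndexParseError(f"unknown affinity unit {unit!r} in {token!r}", line_no)
    return kind, qualifier == "="


def parse_index(text: str) -> list[IndexRecord]:
    """Parse index text into records; '#' lines and '//' tails are comments."""
    records: list[IndexRecord] = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("//")[0].strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 5:
            raise IndexParseError(f"expected >=5 columns, got {len(tokens)}", line_no)
        code, res_tok, year_tok, paff_tok, aff_tok = tokens[:5]
        flags: set[str] = set()
        for extra in tokens[5:]:
            if extra.startswith("flags="):
                flags |= {f for f in extra[6:].split(",") if f}
            else:
                raise IndexParseError(f"unexpected trailing token {extra!r}", line_no)
        try:
            resolution = None if res_tok.upper() == "NMR" else float(res_tok)
            year = int(year_tok)
            p_affinity = float(paff_tok)
        except ValueError as exc:
            raise IndexParseError(f"malformed numeric field: {exc}", line_no) from exc
        kind, exact = _parse_affinity(aff_tok, line_no)
        try:
            records.append(
                IndexRecord(
                    pdb_code=code,
                    resolution=resolution,
                    year=year,
                    p_affinity=p_affinity,
                    measure_kind=kind,
                    exact=exact,
                    flags=flags,
                )
            )
        except ValueError as exc:
            raise IndexParseError(str(exc), line_no) from exc
    return records


def load_annotations(records: list[IndexRecord], csv_text: str) -> list[IndexRecord]:
    """Merge a sidecar annotation CSV (columns: pdb_code, flags) into records.

    ``flags`` is a '|'-separated list; unknown codes in the CSV are ignored
    with a warning so partial annotation files are usable.
    """
    import io

    table = pd.read_csv(io.StringIO(csv_text), dtype=str).fillna("")
    by_code = {r.pdb_code: r for r in records}
    for _, row in table.iterrows():
        code = row["pdb_code"].strip().lower()
        rec = by_code.get(code)
        if rec is None:
            logger.warning("annotation for unknown code %s ignored", code)
            continue
        rec.flags |= {f for f in row["flags"].split("|") if f}
    return records


#: general-set filter reasons, applied sequentially; first match wins
_FILTER_SEQUENCE: tuple[tuple[str, object], ...] = (
    ("non_protein_ligand", lambda r: "non_protein_ligand" in r.flags),
    ("conversion_failed", lambda r: "conversion_failed" in r.flags),
    ("approximate", lambda r: not r.exact),
    ("nmr", lambda r: "nmr" in r.flags),
)


def apply_general_filters(
    records: list[IndexRecord],
) -> tuple[list[IndexRecord], dict[str, int]]:
    """The four general-set filters, in their fixed order.

    Removes non-protein-ligand complexes, conversion failures, approximate
    affinity measurements, and NMR structures.  Returns the retained records
    (input order preserved) and a per-reason removal count; retained plus
    removals always sums to the input count.
    """
    removed = {reason: 0 for reason, _ in _FILTER_SEQUENCE}
    retained: list[IndexRecord] = []
    for rec in records:
        for reason, pred in _FILTER_SEQUENCE:
            if pred(rec):
                removed[reason] += 1
                break
        else:
            retained.append(rec)
    return retained, removed


def is_refined_quality(
    record: IndexRecord,
    resolution_max: float = 2.5,
    strict_resolution: bool = False,
) -> bool:
    """High-quality (refined-set) predicate.

    Resolution "better than 2.5 A" is implemented as <= 2.5 by database
    practice (2.50 A structures are included); ``strict_resolution`` switches
    to a strict <.
    """
    if record.resolution is None or "nmr" in record.flags:
        return False
    res_ok = (
        record.resolution < resolution_max
        if strict_resolution
        else record.resolution <= resolution_max
    )
    return (
        res_ok
        and record.measure_kind in ("Kd", "Ki")
        and record.exact
        and not (record.flags & _STRUCTURAL_DEFECTS)
    )


@dataclass(frozen=True)
class TierSpec:
    """A training-set quality tier: resolution ceiling and/or Kd/Ki-only."""

    resolution_max: float | None = None
    kdki_only: bool = False
    refined_only: bool = False

    def __post_init__(self) -> None:
        if self.refined_only:
            if not self.kdki_only:
                raise ValueError("refined_only implies kdki_only")
            if self.resolution_max is None or self.resolution_max > 2.5:
                raise ValueError("refined_only requires resolution_max <= 2.5")


def make_tier(records: list[IndexRecord], tier: TierSpec) -> list[IndexRecord]:
    """Subset already-general-filtered records by a quality tier."""
    out = []
    for rec in records:
        if tier.resolution_max is not None:
            if rec.resolution is None or rec.resolution > tier.resolution_max:
                continue
        if tier.kdki_only and rec.measure_kind not in ("Kd", "Ki"):
            continue
        if tier.refined_only and not is_refined_quality(rec, tier.resolution_max):
            continue
        out.append(rec)
    return out


def blind_split(new_release: set[str], old_release: set[str]) -> set[str]:
    """Time-stamped blind test set: codes in the new release only."""
    new_norm = {c.lower() for c in new_release}
    old_norm = {c.lower() for c in old_release}
    return new_norm - old_norm


def subtract_codes(records: list[IndexRecord], codes: set[str]) -> list[IndexRecord]:
    """Drop records whose code is in ``codes``; order preserved."""
    drop = {c.lower() for c in codes}
    return [r for r in records if r.pdb_code not in drop]
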