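"""Disease-associated variant bookkeeping.

Parses HUMSAVAR-style tab-text variant tables into :class:`SAPRecord`
objects, summarizes them, and intersects them with the structural coverage
available per protein.  The packaged catalog (``data/table2.tsv``) lists
the 34 aquaporin missense variants associated with genetic disease
(nephrogenic diabetes insipidus for AQP2, Bothnian-type palmoplantar
keratoderma for AQP5, colorectal tumor for AQP8), together with their
structural location and hypothesized defect category; ``data/table1.tsv``
lists the experimental human-aquaporin structures.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Optional, Tuple

from .structure import AA_3TO1

__all__ = [
    "SAPRecord",
    "StructureEntry",
    "CatalogParseError",
    "DEFECT_CATEGORIES",
    "parse_humsavar",
    "format_records",
    "summarize_catalog",
    "filter_uncharacterized",
    "select_modelable",
    "load_table2",
    "load_table1",
]

DEFECT_CATEGORIES = {
    "pore features",
    "tetramer assembly",
    "monomer folding",
    "signal loss",
    "impaired metal binding",
}

_TOKEN_3 = re.compile(r"p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})")
_TOKEN_1 = re.compile(r"^([A-Z])(\d+)([A-Z])$")


class CatalogParseError(ValueError):
    """Malformed variant line; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


@dataclass(frozen=True)
class SAPRecord:
    """One disease-associated single amino acid polymorphism."""

    protein: str
    wt_aa: str
    position: int
    mut_aa: str
    disease: str
    location: str = ""
    defect: str = ""
    motif: str = ""                    # NPA / ar-R when the site is a pore motif
    prior_structural_ref: str = "none"  # none|frick2014|aqp5study|functional-only
    variant_type: str = "disease"

    def __post_init__(self) -> None:
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"synonymous substitution {self}")
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.defect and self.defect not in DEFECT_CATEGORIES:
            raise ValueError(f"unknown defect category {self.defect!r}")

    @property
    def mutation(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"

    def __str__(self) -> str:
        return f"{self.protein}-{self.mutation}"


@dataclass(frozen=True)
class StructureEntry:
    """One experimental structure: protein, PDB id, coverage, quality."""

    protein: str
    pdb_id: str
    residue_range: Tuple[int, int]
    method: str                 # EC | XRD
    resolution: float
    mutation: str = ""
    asymmetric_unit: str = ""
    pore_content: str = ""
    deposition: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.residue_range[0] >= self.residue_range[1]:
            raise ValueError("residue range start must be below end")


def _parse_token(token: str, line_number: int) -> Tuple[str, int, str]:
    token = token.strip()
    m = _TOKEN_3.fullmatch(token)
    if m:
        wt3, pos, mut3 = m.groups()
        wt = AA_3TO1.get(wt3.upper())
        mut = AA_3TO1.get(mut3.upper())
        if wt is None or mut is None:
            raise CatalogParseError(line_number,
                                    f"unknown amino-acid code in {token!r}")
        return wt, int(pos), mut
    m = _TOKEN_1.fullmatch(token)
    if m:
        wt, pos, mut = m.groups()
        if wt not in AA_3TO1.values() or mut not in AA_3TO1.values():
            raise CatalogParseError(line_number,
                                    f"unknown amino-acid code in {token!r}")
        return wt, int(pos), mut
    raise CatalogParseError(line_number, f"malformed substitution token {token!r}")


def parse_humsavar(text: str) -> List[SAPRecord]:
    """Parse tab-delimited variant lines into records.

    Accepts both the packaged catalog layout (header line ``protein\\t
    mutation\\t...``) and loose HUMSAVAR-style lines whose fields include a
    gene name, a substitution token (``p.Leu22Val`` or ``L22V``) and a
    disease string.  Synonymous lines are rejected with a warning;
    malformed tokens raise :class:`CatalogParseError` with the line number.
    """
    records: List[SAPRecord] = []
    header: Optional[List[str]] = None
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None and fields[0].strip().lower() == "protein":
            header = [f.strip().lower() for f in fields]
            continue
        if header is not None:
            row = dict(zip(header, (f.strip() for f in fields)))
            wt, pos, mut = _parse_token(row["mutation"], ln)
            if wt == mut:
                warnings.warn(f"line {ln}: synonymous substitution skipped")
                continue
            records.append(SAPRecord(
                protein=row["protein"], wt_aa=wt, position=pos, mut_aa=mut,
                disease=row.get("disease", ""),
                location=row.get("location", ""),
                defect=row.get("defect", ""),
                motif=row.get("motif", ""),
                prior_structural_ref=row.get("prior_structural_ref", "none"),
                variant_type=row.get("variant_type", "disease"),
            ))
            continue
        # loose HUMSAVAR-ish dialect: gene ... token ... disease
        token_idx = None
        for i, f in enumerate(fields):
            f = f.strip()
            if _TOKEN_3.fullmatch(f) or _TOKEN_1.fullmatch(f):
                token_idx = i
                break
        if token_idx is None:
            raise CatalogParseError(ln, "no substitution token found")
        wt, pos, mut = _parse_token(fields[token_idx].strip(), ln)
        if wt == mut:
            warnings.warn(f"line {ln}: synonymous substitution skipped")
            continue
        protein = fields[0].strip()
        disease = fields[-1].strip() if len(fields) > token_idx + 1 else ""
        records.append(SAPRecord(protein=protein, wt_aa=wt, position=pos,
                                 mut_aa=mut, disease=disease))
    return records


def format_records(records: Iterable[SAPRecord]) -> str:
    """Serialize records to the packaged tab-text layout (round-trips)."""
    cols = ["protein", "mutation", "disease", "location", "defect", "motif",
            "prior_structural_ref", "variant_type"]
    lines = ["\t".join(cols)]
    for r in records:
        lines.append("\t".join([
            r.protein, r.mutation, r.disease, r.location, r.defect, r.motif,
            r.prior_structural_ref, r.variant_type,
        ]))
    return "\n".join(lines) + "\n"


def summarize_catalog(records: List[SAPRecord]) -> Dict[str, Dict[str, int]]:
    """Counts per protein, disease and defect category.

    Records are ordered by protein then position before counting so the
    summary ordering is deterministic; each counter sums to len(records)
    (defect counts only over records carrying a category).
    """
    if not records:
        raise ValueError("cannot summarize an empty record set")
    ordered = sorted(records, key=lambda r: (r.protein, r.position))
    summary = {
        "protein": dict(Counter(r.protein for r in ordered)),
        "disease": dict(Counter(r.disease for r in ordered)),
        "defect": dict(Counter(r.defect for r in ordered if r.defect)),
    }
    return summary


def filter_uncharacterized(records: Iterable[SAPRecord]) -> List[SAPRecord]:
    """Variants without a prior structural characterization.

    Keeps records whose only prior reference is functional (or none):
    these are the ones needing fresh structural analysis.
    """
    return [r for r in records
            if r.prior_structural_ref in ("none", "functional-only")]


def select_modelable(records: Iterable[SAPRecord],
                     coverage: Dict[str, Tuple[int, int]]) -> List[SAPRecord]:
    """Records whose position falls inside per-protein structural coverage.

    *coverage* maps protein name to the (start, end) author-numbered
    interval with coordinates; proteins absent from the map are skipped
    with a warning.
    """
    out = []
    warned = set()
    for r in records:
        if r.protein not in coverage:
            if r.protein not in warned:
                warnings.warn(f"no structural coverage for {r.protein}; skipped")
                warned.add(r.protein)
            continue
        start, end = coverage[r.protein]
        if start <= r.position <= end:
            out.append(r)
    return out


def _read_packaged(name: str) -> str:
    return resources.files("aquadefect.data").joinpath(name).read_text()


def load_table2() -> List[SAPRecord]:
    """The packaged 34-variant disease catalog."""
    return parse_humsavar(_read_packaged("table2.tsv"))


def load_table1() -> List[StructureEntry]:
    """The packaged table of experimental human-aquaporin structures."""
    entries = []
    lines = _read_packaged("table1.tsv").splitlines()
    header = [h.strip().lower() for h in lines[0].split("\t")]
    for raw in lines[1:]:
        if not raw.strip() or raw.startswith("#"):
            continue
        row = dict(zip(header, (f.strip() for f in raw.split("\t"))))
        start, end = row["residue_range"].split("-")
        entries.append(StructureEntry(
            protein=row["protein"], pdb_id=row["pdb_id"],
            residue_range=(int(start), int(end)), method=row["method"],
            resolution=float(row["resolution"]),
            mutation="" if row["mutation"] in ("-", "--") else row["mutation"],
            asymmetric_unit=row.get("asymmetric_unit", ""),
            pore_content="" if row.get("pore", "-") in ("-", "--")
            else row.get("pore", ""),
            deposition=int(row.get("deposition", 0)),
        ))
    return entries
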