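"""Domain types and IO for multilocus microsatellite genotype tables.

A genotype table is delimited text (comma or tab, auto-detected) with a
header row naming an individual-id column followed by one column per locus.
Cells use the syntax ``a1/a2`` where each slot is an integer fragment length
in base pairs or a missing marker (``-``, ``.``, or empty; typographic
dashes are accepted on input).  Allele order within a cell is normalized
ascending on read so that genotypes compare as unordered pairs.
"""
from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .errors import (
    CapacityError,
    ParseError,
    SchemaError,
    ValidationError,
)

#: tokens accepted as a missing allele slot on input
MISSING_TOKENS = {"", "-", "−", "–", "—", ".", "na", "NA"}
#: token emitted for a missing allele slot on output
MISSING_OUT = "-"

ROLES = ("dam", "sire", "offspring", "unknown")


@dataclass(frozen=True)
class LocusGenotype:
    """An unordered pair of allele calls at one locus; slots may be missing.

    States: *full* (both alleles known), *half* (one known allele plus one
    wildcard slot, printed ``194/-``) and *missing* (printed ``-/-``).
    Known alleles are stored ascending, missing slots last, so equality and
    hashing are order-insensitive.
    """

    a1: Optional[int] = None
    a2: Optional[int] = None

    def __post_init__(self) -> None:
        known = []
        for a in (self.a1, self.a2):
            if a is None:
                continue
            a = int(a)
            if a <= 0:
                raise ValidationError(f"allele must be a positive integer, got {a!r}")
            known.append(a)
        known.sort()
        norm = tuple(known) + (None,) * (2 - len(known))
        object.__setattr__(self, "a1", norm[0])
        object.__setattr__(self, "a2", norm[1])

    # -- state predicates -------------------------------------------------
    @property
    def known_alleles(self) -> tuple[int, ...]:
        return tuple(a for a in (self.a1, self.a2) if a is not None)

    @property
    def is_missing(self) -> bool:
        return self.a1 is None and self.a2 is None

    @property
    def is_full(self) -> bool:
        return self.a1 is not None and self.a2 is not None

    @property
    def is_half(self) -> bool:
        return (self.a1 is None) != (self.a2 is None)

    @property
    def has_wildcard(self) -> bool:
        """True when at least one slot is unknown (missing or half state)."""
        return self.a1 is None or self.a2 is None

    @property
    def is_homozygous(self) -> bool:
        return self.is_full and self.a1 == self.a2

    def contains(self, allele: int) -> bool:
        return allele in self.known_alleles

    # -- text form --------------------------------------------------------
    @classmethod
    def parse(cls, cell: str, *, row: str = "?", column: str = "?") -> "LocusGenotype":
        parts = [p.strip() for p in str(cell).strip().split("/")]
        if len(parts) == 1:
            parts = parts * 2  # a bare "-" means -/-
        if len(parts) != 2:
            raise ParseError(
                f"cell {cell!r} at row {row!r}, column {column!r}: expected 'a1/a2'"
            )
        slots = []
        for p in parts:
            if p in MISSING_TOKENS:
                slots.append(None)
            else:
                try:
                    slots.append(int(p))
                except ValueError:
                    raise ParseError(
                        f"non-integer allele token {p!r} at row {row!r}, column {column!r}"
                    ) from None
        return cls(*slots)

    def format(self) -> str:
        def tok(a: Optional[int]) -> str:
            return MISSING_OUT if a is None else str(a)

        return f"{tok(self.a1)}/{tok(self.a2)}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()


MISSING_GENOTYPE = LocusGenotype()


@dataclass(frozen=True)
class Panel:
    """Ordered list of locus names genotyped for every individual."""

    loci: tuple[str, ...]

    def __post_init__(self) -> None:
        loci = tuple(str(l) for l in self.loci)
        if not loci:
            raise ValidationError("panel must declare at least one locus")
        if any(not name for name in loci):
            raise ValidationError("locus names must be non-empty")
        if len(set(loci)) != len(loci):
            raise ValidationError("locus names must be unique")
        object.__setattr__(self, "loci", loci)

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __contains__(self, name: str) -> bool:
        return name in self.loci

    @classmethod
    def from_yaml(cls, path) -> "Panel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, Mapping) or "loci" not in doc:
            raise SchemaError(f"panel file {path} must map a 'loci' key to a list")
        return cls(tuple(doc["loci"]))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"loci": list(self.loci)}, fh, sort_keys=False)


@dataclass(frozen=True)
class MultilocusGenotype:
    """Per-individual map locus name -> :class:`LocusGenotype`."""

    individual_id: str
    genotypes: Mapping[str, LocusGenotype]
    role: str = "unknown"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"role must be one of {ROLES}, got {self.role!r}")
        object.__setattr__(self, "genotypes", dict(self.genotypes))

    def validate_panel(self, panel: Panel) -> None:
        got = set(self.genotypes)
        expected = set(panel.loci)
        if got != expected:
            raise SchemaError(
                f"individual {self.individual_id!r}: loci {sorted(got)} "
                f"do not match panel {sorted(expected)}"
            )

    def locus(self, name: str) -> LocusGenotype:
        return self.genotypes[name]

    def n_missing(self) -> int:
        return sum(1 for g in self.genotypes.values() if g.is_missing)

    def n_scored(self) -> int:
        return sum(1 for g in self.genotypes.values() if not g.is_missing)

    def is_fully_homozygous(self) -> bool:
        return all(g.is_homozygous for g in self.genotypes.values() if not g.is_missing)

    def with_role(self, role: str) -> "MultilocusGenotype":
        return MultilocusGenotype(self.individual_id, self.genotypes, role)


# ---------------------------------------------------------------------------
# delimited genotype tables
# ---------------------------------------------------------------------------


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_genotype_table(path, panel: Panel, role: str = "unknown") -> list[MultilocusGenotype]:
    """Read a delimited genotype table against a declared panel.

    The header must name the id column first, then exactly the panel's loci
    (any order).  Unknown loci raise :class:`SchemaError`; malformed cells
    raise :class:`ParseError` naming row and column; duplicated ids raise
    :class:`ValidationError`.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise SchemaError(f"{path}: empty file, expected a header row")
    delim = _sniff_delimiter(lines[0])
    reader = csv.reader(io.StringIO("\n".join(lines)), delimiter=delim)
    header = [h.strip() for h in next(reader)]
    if len(header) < 2:
        raise SchemaError(f"{path}: header must name an id column and at least one locus")
    locus_cols = header[1:]
    unknown = [c for c in locus_cols if c not in panel]
    if unknown:
        raise SchemaError(f"{path}: unknown loci in header: {unknown}")
    absent = [l for l in panel.loci if l not in locus_cols]
    if absent:
        raise SchemaError(f"{path}: header is missing panel loci: {absent}")
    if len(set(locus_cols)) != len(locus_cols):
        raise SchemaError(f"{path}: duplicated locus column in header")

    individuals: list[MultilocusGenotype] = []
    seen: set[str] = set()
    for cells in reader:
        if not cells or all(not c.strip() for c in cells):
            continue
        ind_id = cells[0].strip()
        if ind_id in seen:
            raise ValidationError(f"{path}: duplicate individual id {ind_id!r}")
        seen.add(ind_id)
        if len(cells) != len(header):
            raise ParseError(
                f"{path}: row {ind_id!r} has {len(cells)} cells, expected {len(header)}"
            )
        genotypes = {
            locus: LocusGenotype.parse(cell, row=ind_id, column=locus)
            for locus, cell in zip(locus_cols, cells[1:])
        }
        # store in panel order regardless of header order
        ordered = {locus: genotypes[locus] for locus in panel.loci}
        individuals.append(MultilocusGenotype(ind_id, ordered, role))
    return individuals


def write_genotype_table(
    individuals: Iterable[MultilocusGenotype],
    path,
    panel: Panel,
    delimiter: str = ",",
) -> None:
    """Write individuals to a delimited table in panel order."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["individual_id", *panel.loci])
        for ind in individuals:
            ind.validate_panel(panel)
            writer.writerow(
                [ind.individual_id, *(ind.genotypes[l].format() for l in panel.loci)]
            )


# ---------------------------------------------------------------------------
# Genepop export / import
# ---------------------------------------------------------------------------


def allele_code_map(
    individuals: Sequence[MultilocusGenotype], panel: Panel
) -> dict[str, dict[int, int]]:
    """Stable per-locus allele -> 3-digit code map (codes assigned by rank)."""
    codes: dict[str, dict[int, int]] = {}
    for locus in panel.loci:
        alleles = sorted(
            {a for ind in individuals for a in ind.genotypes[locus].known_alleles}
        )
        if len(alleles) > 999:
            raise CapacityError(
                f"locus {locus!r} has {len(alleles)} alleles; Genepop allows 999"
            )
        codes[locus] = {a: i + 1 for i, a in enumerate(alleles)}
    return codes


def write_genepop(
    individuals: Sequence[MultilocusGenotype],
    path,
    panel: Optional[Panel] = None,
    title: str = "parthenotrace export",
) -> Path:
    """Write a Genepop file plus a ``<path>.codes.tsv`` sidecar code map.

    Missing allele slots are coded ``000``.  Returns the sidecar path.
    """
    individuals = list(individuals)
    if panel is None:
        if not individuals:
            raise UsageErrorNoPanel()
        panel = Panel(tuple(individuals[0].genotypes))
    for ind in individuals:
        ind.validate_panel(panel)
    codes = allele_code_map(individuals, panel)

    path = Path(path)
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in panel.loci:
            fh.write(locus + "\n")
        fh.write("Pop\n")
        for ind in individuals:
            pairs = []
            for locus in panel.loci:
                g = ind.genotypes[locus]
                c1 = codes[locus].get(g.a1, 0) if g.a1 is not None else 0
                c2 = codes[locus].get(g.a2, 0) if g.a2 is not None else 0
                pairs.append(f"{c1:03d}{c2:03d}")
            fh.write(f"{ind.individual_id} , " + " ".join(pairs) + "\n")

    sidecar = Path(str(path) + ".codes.tsv")
    with open(sidecar, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["locus", "allele", "code"])
        for locus in panel.loci:
            for allele, code in codes[locus].items():
                writer.writerow([locus, allele, f"{code:03d}"])
    return sidecar


class UsageErrorNoPanel(SchemaError):
    def __init__(self) -> None:  # pragma: no cover - trivial
        super().__init__("cannot derive a panel from an empty collection; pass panel=")


def read_genepop(path, codes_path=None, role: str = "unknown") -> list[MultilocusGenotype]:
    """Re-read a Genepop file written by :func:`write_genepop`."""
    path = Path(path)
    if codes_path is None:
        codes_path = Path(str(path) + ".codes.tsv")
    decode: dict[str, dict[int, int]] = {}
    with open(codes_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for rec in reader:
            decode.setdefault(rec["locus"], {})[int(rec["code"])] = int(rec["allele"])

    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines()]
    loci: list[str] = []
    i = 1  # skip title
    while i < len(lines) and lines[i].strip().lower() != "pop":
        loci.extend(l.strip() for l in lines[i].split(",") if l.strip())
        i += 1
    individuals = []
    for line in lines[i + 1 :]:
        if not line.strip():
            continue
        if line.strip().lower() == "pop":
            continue
        ident, _, body = line.partition(",")
        tokens = body.split()
        genotypes = {}
        for locus, tok in zip(loci, tokens):
            c1, c2 = int(tok[:3]), int(tok[3:])
            a1 = decode.get(locus, {}).get(c1) if c1 else None
            a2 = decode.get(locus, {}).get(c2) if c2 else None
            genotypes[locus] = LocusGenotype(a1, a2)
        individuals.append(MultilocusGenotype(ident.strip(), genotypes, role))
    return individuals
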