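"""Catalog of the Dw1-Dw3 dwarfing loci, their detection primers, and the
nine known mutant-allele signatures.

Coordinates are 1-based, inclusive, and relative to the "A" of the ATG start
codon of the wild-type gene sequence.  That convention is used everywhere in
the package; conversion to 0-based slicing happens only at the point of use.

The packaged default catalog covers:

* ``dw1``  — T at position 1350 of Sobic.009G229800 (any other base is
  wild type);
* ``dw2``  — GA deletion at 549-550 of Sobic.006G067700;
* seven ``dw3`` alleles of Sobic.007G163800: the 882-bp *ref* insertion at
  6204-7085, single-base substitutions *a* (A>C at 5406) and *b* (A>G at
  5668), deletions *c* (5967-5968), *sd3* (5485-5566) and *sd5* (5997-6011),
  and the 6-bp tandem duplication *sd4* (5820-5825).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable

from .errors import NotFoundError

DNA_ALPHABET = frozenset("ACGT")

SIGNATURE_KINDS = ("substitution", "deletion", "insertion", "duplication")


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair, both written 5'->3'."""

    forward: str
    reverse: str


@dataclass(frozen=True)
class MutationSignature:
    """The defining DNA change of a mutant allele.

    ``start``/``end`` are 1-based inclusive ATG-relative positions.  For a
    substitution they are equal; for a deletion they delimit the deleted
    reference interval; for an insertion they delimit the interval the
    inserted bases occupy in the mutant sequence (so ``start`` is the
    position immediately after the last conserved reference base); for a
    duplication they delimit the duplicated reference interval.  ``alt``
    holds inserted/substituted bases when they are known, else "".
    """

    kind: str
    start: int
    end: int
    length: int
    alt: str = ""


@dataclass(frozen=True)
class Locus:
    name: str
    gene_id: str
    primer_pair: PrimerPair
    wild_type_amplicon_length: int


@dataclass(frozen=True)
class AlleleDefinition:
    allele_name: str
    locus_name: str
    signature: MutationSignature
    expected_amplicon_length: int | None = None


@dataclass(frozen=True)
class AlleleCatalog:
    loci: tuple[Locus, ...]
    alleles: tuple[AlleleDefinition, ...]

    def locus(self, name: str) -> Locus:
        for locus in self.loci:
            if locus.name == name:
                return locus
        raise NotFoundError(
            f"unknown locus {name!r}; valid loci: {[l.name for l in self.loci]}"
        )

    def alleles_for(self, locus_name: str) -> tuple[AlleleDefinition, ...]:
        return tuple(a for a in self.alleles if a.locus_name == locus_name)

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.loci)


@dataclass(frozen=True)
class ValidationCheck:
    subject: str
    check: str
    passed: bool
    detail: str = ""


@dataclass
class ValidationReport:
    checks: list[ValidationCheck] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> list[ValidationCheck]:
        return [c for c in self.checks if not c.passed]


def lookup_allele(catalog: AlleleCatalog, allele_name: str) -> AlleleDefinition:
    """Return the definition of ``allele_name`` or raise :class:`NotFoundError`."""
    for allele in catalog.alleles:
        if allele.allele_name == allele_name:
            return allele
    valid = [a.allele_name for a in catalog.alleles]
    raise NotFoundError(f"unknown allele {allele_name!r}; valid alleles: {valid}")


def validate_catalog(catalog: AlleleCatalog) -> ValidationReport:
    """Check the structural invariants of a catalog.

    Failures are reported, never raised, so a partially broken user-supplied
    catalog file can be diagnosed in one pass.
    """
    report = ValidationReport()
    add = report.checks.append

    names = [l.name for l in catalog.loci]
    add(ValidationCheck("catalog", "locus names unique", len(set(names)) == len(names)))
    for locus in catalog.loci:
        for which in ("forward", "reverse"):
            seq = getattr(locus.primer_pair, which)
            add(
                ValidationCheck(
                    locus.name,
                    f"{which} primer alphabet/length",
                    bool(seq) and set(seq) <= DNA_ALPHABET and 18 <= len(seq) <= 25,
                    seq,
                )
            )
        add(
            ValidationCheck(
                locus.name,
                "wild-type amplicon length > 0",
                locus.wild_type_amplicon_length > 0,
            )
        )

    allele_names = [a.allele_name for a in catalog.alleles]
    add(
        ValidationCheck(
            "catalog",
            "allele names unique",
            len(set(allele_names)) == len(allele_names),
        )
    )
    for allele in catalog.alleles:
        sig = allele.signature
        add(
            ValidationCheck(
                allele.allele_name,
                "locus exists",
                allele.locus_name in names,
                allele.locus_name,
            )
        )
        add(
            ValidationCheck(
                allele.allele_name,
                "signature kind recognised",
                sig.kind in SIGNATURE_KINDS,
                sig.kind,
            )
        )
        if sig.kind == "substitution":
            ok = sig.start == sig.end and sig.length == 1 and len(sig.alt) == 1
            add(ValidationCheck(allele.allele_name, "substitution is single-base", ok))
        elif sig.kind == "deletion":
            ok = sig.end - sig.start + 1 == sig.length
            add(
                ValidationCheck(
                    allele.allele_name,
                    "end-start+1 == length",
                    ok,
                    f"{sig.end}-{sig.start}+1 vs {sig.length}",
                )
            )
        elif sig.kind in ("insertion", "duplication"):
            ok = sig.end - sig.start + 1 == sig.length
            add(
                ValidationCheck(
                    allele.allele_name,
                    "end-start+1 == length",
                    ok,
                    f"{sig.end}-{sig.start}+1 vs {sig.length}",
                )
            )
            if sig.alt:
                add(
                    ValidationCheck(
                        allele.allele_name,
                        "alt length matches signature length",
                        len(sig.alt) == sig.length,
                    )
                )
        if sig.alt:
            add(
                ValidationCheck(
                    allele.allele_name,
                    "alt alphabet",
                    set(sig.alt) <= DNA_ALPHABET,
                )
            )
    return report


# ---------------------------------------------------------------------------
# JSON (de)serialisation


def catalog_to_dict(catalog: AlleleCatalog) -> dict:
    return {
        "loci": [asdict(l) for l in catalog.loci],
        "alleles": [asdict(a) for a in catalog.alleles],
    }


def catalog_from_dict(data: dict) -> AlleleCatalog:
    loci = tuple(
        Locus(
            name=l["name"],
            gene_id=l["gene_id"],
            primer_pair=PrimerPair(**l["primer_pair"]),
            wild_type_amplicon_length=int(l["wild_type_amplicon_length"]),
        )
        for l in data["loci"]
    )
    alleles = tuple(
        AlleleDefinition(
            allele_name=a["allele_name"],
            locus_name=a["locus_name"],
            signature=MutationSignature(**a["signature"]),
            expected_amplicon_length=a.get("expected_amplicon_length"),
        )
        for a in data["alleles"]
    )
    return AlleleCatalog(loci=loci, alleles=alleles)


def save_catalog(catalog: AlleleCatalog, path: str | Path) -> None:
    Path(path).write_text(json.dumps(catalog_to_dict(catalog), indent=2) + "\n")


def load_catalog(path: str | Path) -> AlleleCatalog:
    return catalog_from_dict(json.loads(Path(path).read_text()))


def default_catalog() -> AlleleCatalog:
    """The packaged catalog of the three loci and nine mutant alleles."""
    text = resources.files("dwarfcall.data").joinpath("catalog.json").read_text()
    return catalog_from_dict(json.loads(text))
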