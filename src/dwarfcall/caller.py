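"""Signature-based allele calling for the Dw1-Dw3 dwarfing loci.

The calling pipeline per haplotype is: in-silico PCR of the locus, product
size prescreen (Dw3 only), global pairwise alignment of the product against
the wild-type amplicon, extraction of left-normalized variants, and matching
of those variants against the mutation-signature catalog.  Two haplotype
sequences per locus express every zygosity (a single sequence is treated as
homozygous); per-locus diploid calls are composed into the conventional
genotype nomenclature, e.g. ``dw1Dw2dw3-ref`` for a line homozygous mutant
at Dw1 and Dw3 and wild type at Dw2, and ``Dw1dw1`` for a heterozygote.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align, SeqIO

from .catalog import AlleleCatalog, AlleleDefinition, Locus, MutationSignature
from .errors import (
    DwarfcallError,
    GenotypeParseError,
    InvalidInputError,
    NotFoundError,
)
from .insilico_pcr import (
    DEFAULT_PRESCREEN_THRESHOLD,
    INSERTION_CLASS,
    Amplicon,
    Template,
    amplify,
    dw3_size_prescreen,
)

WILD_TYPE = "WT"
UNKNOWN = "unknown"

ZYG_HOM_WT = "homozygous_wt"
ZYG_HET = "heterozygous"
ZYG_HOM_MUT = "homozygous_mutant"
ZYG_COMPOUND = "compound"

SUBSTITUTION = "substitution"
DELETION = "deletion"
INSERTION = "insertion"


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap scoring for the amplicon-vs-reference alignment.

    Defaults make each catalog indel align as a single gap event rather
    than scattered mismatches.  Gap of length L scores
    ``gap_open + (L - 1) * gap_extend``.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -6.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of an amplicon (query) to the wild-type amplicon
    region (reference), with ``ref_offset`` the ATG-relative position of the
    first reference column."""

    query_aligned: str
    ref_aligned: str
    ref_offset: int
    score: float


@dataclass(frozen=True)
class Variant:
    """A left-normalized difference from the wild-type reference.

    ``position`` is 1-based ATG-relative: for a substitution or deletion the
    first affected reference base, for an insertion the position the first
    inserted base would occupy (i.e. insertion between reference positions
    ``position - 1`` and ``position``)."""

    position: int
    kind: str
    ref_allele: str = ""
    alt_allele: str = ""

    @property
    def ref_end(self) -> int:
        """Last reference position touched (== position for insertions)."""
        return self.position + max(len(self.ref_allele) - 1, 0)


@dataclass(frozen=True)
class AlleleCall:
    allele_name: str | None
    supporting_variants: tuple[Variant, ...] = ()
    prescreen: str | None = None
    status: str = "ok"
    reason: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "ok"


@dataclass(frozen=True)
class LocusGenotype:
    locus_name: str
    allele_a: AlleleCall
    allele_b: AlleleCall
    zygosity: str | None


@dataclass
class SampleGenotype:
    sample_id: str
    loci: dict[str, LocusGenotype] = field(default_factory=dict)
    genotype_string: str = ""


# ---------------------------------------------------------------------------
# Alignment and variant extraction


def align_amplicon(
    query: str,
    reference_segment: str,
    ref_offset: int,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> PairwiseAlignment:
    """Globally align an amplicon to the wild-type amplicon segment."""
    if not query or not reference_segment:
        raise InvalidInputError("cannot align empty sequences")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    aln = aligner.align(reference_segment, query)[0]
    return PairwiseAlignment(
        query_aligned=aln[1],
        ref_aligned=aln[0],
        ref_offset=ref_offset,
        score=aln.score,
    )


def _left_normalize_deletion(ref: str, ref_offset: int, pos: int, length: int) -> int:
    """Shift a deletion of ``length`` bases starting at ATG position ``pos``
    to its leftmost equivalent placement."""
    while pos - 1 >= ref_offset and ref[pos - 1 - ref_offset] == ref[pos + length - 1 - ref_offset]:
        pos -= 1
    return pos


def _left_normalize_insertion(
    ref: str, ref_offset: int, pos: int, alt: str
) -> tuple[int, str]:
    """Shift an insertion (between ``pos - 1`` and ``pos``) left while the
    base preceding the insertion point equals the insertion's last base."""
    while pos - 1 >= ref_offset and ref[pos - 1 - ref_offset] == alt[-1]:
        alt = ref[pos - 1 - ref_offset] + alt[:-1]
        pos -= 1
    return pos, alt


def variants_from_alignment(aln: PairwiseAlignment) -> list[Variant]:
    """Extract variants from an alignment, merging adjacent gap columns into
    single indels and left-normalizing indels against the reference."""
    ref = aln.ref_aligned.replace("-", "")
    variants: list[Variant] = []
    ref_pos = aln.ref_offset
    i = 0
    n = len(aln.ref_aligned)
    while i < n:
        r = aln.ref_aligned[i]
        q = aln.query_aligned[i]
        if r == "-":
            j = i
            while j < n and aln.ref_aligned[j] == "-":
                j += 1
            alt = aln.query_aligned[i:j]
            pos, alt = _left_normalize_insertion(ref, aln.ref_offset, ref_pos, alt)
            variants.append(Variant(position=pos, kind=INSERTION, alt_allele=alt))
            i = j
        elif q == "-":
            j = i
            while j < n and aln.query_aligned[j] == "-" and aln.ref_aligned[j] != "-":
                j += 1
            length = j - i
            pos = _left_normalize_deletion(ref, aln.ref_offset, ref_pos, length)
            deleted = ref[pos - aln.ref_offset : pos - aln.ref_offset + length]
            variants.append(Variant(position=pos, kind=DELETION, ref_allele=deleted))
            ref_pos += length
            i = j
        else:
            if r != q:
                variants.append(
                    Variant(position=ref_pos, kind=SUBSTITUTION, ref_allele=r, alt_allele=q)
                )
            ref_pos += 1
            i += 1
    variants.sort(key=lambda v: v.position)
    return variants


# ---------------------------------------------------------------------------
# Signature matching


def _variant_matches_signature(
    variant: Variant,
    sig: MutationSignature,
    position_tolerance: int,
    insertion_length_tolerance: int,
) -> bool:
    near = abs(variant.position - sig.start) <= position_tolerance
    if sig.kind == "substitution":
        return (
            variant.kind == SUBSTITUTION and near and variant.alt_allele == sig.alt
        )
    if sig.kind == "deletion":
        return (
            variant.kind == DELETION
            and near
            and len(variant.ref_allele) == sig.length
        )
    if sig.kind == "insertion":
        # the inserted content may be unknown (catalog alt empty); identity
        # then rests on position plus insertion length
        return (
            variant.kind == INSERTION
            and near
            and abs(len(variant.alt_allele) - sig.length) <= insertion_length_tolerance
            and (not sig.alt or variant.alt_allele == sig.alt)
        )
    if sig.kind == "duplication":
        # a tandem duplication presents as an insertion whose leftmost
        # placement starts at the first base of the duplicated interval
        return (
            variant.kind == INSERTION
            and near
            and len(variant.alt_allele) == sig.length
            and (not sig.alt or variant.alt_allele == sig.alt)
        )
    return False


def _coincides(variant: Variant, sig: MutationSignature, pad: int) -> bool:
    return variant.position <= sig.end + pad and variant.ref_end >= sig.start - pad


def match_signatures(
    variants: Sequence[Variant],
    catalog: AlleleCatalog,
    locus_name: str,
    position_tolerance: int = 0,
    insertion_length_tolerance: int = 10,
) -> AlleleCall:
    """Match extracted variants against the catalog signatures of a locus.

    Returns wild type when no variant coincides with any signature interval;
    the unique satisfied allele when exactly one signature is matched;
    ``unknown`` when variants sit at/near signature positions but satisfy no
    signature, or when two signatures are satisfied at once (never an
    arbitrary pick).  Variants away from every signature (e.g. sequencing
    noise) do not affect the call.
    """
    alleles = catalog.alleles_for(locus_name)
    if not alleles:
        raise NotFoundError(f"no catalog alleles for locus {locus_name!r}")
    matched: list[tuple[AlleleDefinition, list[Variant]]] = []
    for allele in alleles:
        support = [
            v
            for v in variants
            if _variant_matches_signature(
                v, allele.signature, position_tolerance, insertion_length_tolerance
            )
        ]
        if support:
            matched.append((allele, support))
    if len(matched) == 1:
        allele, support = matched[0]
        return AlleleCall(allele.allele_name, tuple(support))
    coinciding = [
        v
        for v in variants
        if any(_coincides(v, a.signature, position_tolerance) for a in alleles)
    ]
    if len(matched) > 1:
        return AlleleCall(
            UNKNOWN,
            tuple(coinciding),
            reason="multiple signatures matched: "
            + ", ".join(a.allele_name for a, _ in matched),
        )
    if coinciding:
        return AlleleCall(
            UNKNOWN, tuple(coinciding), reason="unmatched variants at signature sites"
        )
    return AlleleCall(WILD_TYPE, ())


# ---------------------------------------------------------------------------
# Haplotype and sample calling


def call_haplotype(
    sequence: str,
    locus: Locus,
    catalog: AlleleCatalog,
    reference: Template,
    *,
    max_mismatch: int = 0,
    prescreen_threshold: int = DEFAULT_PRESCREEN_THRESHOLD,
    scoring: AlignmentScoring = AlignmentScoring(),
    position_tolerance: int = 0,
    insertion_length_tolerance: int = 10,
) -> AlleleCall:
    """Run the full pipeline on one haplotype sequence of one locus."""
    try:
        ref_amp = amplify(reference, locus, max_mismatch)
        sample_amp = amplify(
            Template(id="query", sequence=sequence), locus, max_mismatch
        )
    except DwarfcallError as exc:
        return AlleleCall(None, status="failed", reason=str(exc))
    prescreen = None
    if locus.name == "Dw3":
        prescreen = dw3_size_prescreen(sample_amp.length, prescreen_threshold)
    aln = align_amplicon(
        sample_amp.sequence, ref_amp.sequence, ref_amp.template_start, scoring
    )
    variants = variants_from_alignment(aln)
    call = match_signatures(
        variants, catalog, locus.name, position_tolerance, insertion_length_tolerance
    )
    return AlleleCall(
        call.allele_name,
        call.supporting_variants,
        prescreen=prescreen,
        status=call.status,
        reason=call.reason,
    )


def _zygosity(name_a: str | None, name_b: str | None) -> str | None:
    if name_a in (None, UNKNOWN) or name_b in (None, UNKNOWN):
        return None
    if name_a == WILD_TYPE and name_b == WILD_TYPE:
        return ZYG_HOM_WT
    if WILD_TYPE in (name_a, name_b):
        return ZYG_HET
    if name_a == name_b:
        return ZYG_HOM_MUT
    return ZYG_COMPOUND


def call_sample(
    sample_id: str,
    haplotypes: Mapping[str, Sequence[str]],
    catalog: AlleleCatalog,
    references: Mapping[str, Template],
    *,
    _cache: dict | None = None,
    **call_kwargs,
) -> SampleGenotype:
    """Call all three loci of one sample from one or two haplotype sequences
    per locus (a single sequence is treated as homozygous).

    ``_cache`` optionally memoizes haplotype calls across samples, keyed by
    ``(locus, sequence)`` — panels share haplotypes heavily.
    """
    genotype = SampleGenotype(sample_id=sample_id)
    for locus_name in catalog.locus_names:
        seqs = list(haplotypes.get(locus_name, ()))
        if not seqs or len(seqs) > 2:
            failed = AlleleCall(
                None,
                status="failed",
                reason=f"expected 1-2 haplotypes for {locus_name}, got {len(seqs)}",
            )
            genotype.loci[locus_name] = LocusGenotype(locus_name, failed, failed, None)
            continue
        if len(seqs) == 1:
            seqs = [seqs[0], seqs[0]]
        locus = catalog.locus(locus_name)
        reference = references[locus_name]
        calls = []
        for seq in seqs:
            key = (locus_name, seq)
            if _cache is not None and key in _cache:
                calls.append(_cache[key])
                continue
            call = call_haplotype(seq, locus, catalog, reference, **call_kwargs)
            if _cache is not None:
                _cache[key] = call
            calls.append(call)
        a, b = calls
        genotype.loci[locus_name] = LocusGenotype(
            locus_name, a, b, _zygosity(a.allele_name, b.allele_name)
        )
    try:
        genotype.genotype_string = format_genotype(genotype)
    except InvalidInputError:
        genotype.genotype_string = ""
    return genotype


def call_panel(
    haplotypes: Mapping[str, Mapping[str, Sequence[str]]],
    catalog: AlleleCatalog,
    references: Mapping[str, Template],
    **call_kwargs,
) -> list[SampleGenotype]:
    """Call every sample of a panel, memoizing shared haplotype sequences."""
    cache: dict = {}
    return [
        call_sample(sid, haps, catalog, references, _cache=cache, **call_kwargs)
        for sid, haps in haplotypes.items()
    ]


# ---------------------------------------------------------------------------
# Genotype nomenclature

_LOCUS_ORDER = ("Dw1", "Dw2", "Dw3")

# mutant dw3 tokens carry a suffix (dw3-ref, dw3-sd3, ...); the tempered
# pattern stops the suffix from swallowing a following "dw3..." token
_TOKEN_PATTERNS = {
    "Dw1": (r"Dw1", r"dw1"),
    "Dw2": (r"Dw2", r"dw2"),
    "Dw3": (r"Dw3", r"dw3(?:-(?:(?!dw\d)[a-z0-9])+)?"),
}


def format_genotype(g: SampleGenotype) -> str:
    """Render a sample genotype in the conventional nomenclature.

    Homozygous loci render as a single token (``dw1``, ``Dw2``, ``dw3-ref``),
    heterozygous loci as wild-type-plus-mutant (``Dw1dw1``), compound
    heterozygotes as a slash pair (``dw3-a/dw3-b``); locus order Dw1, Dw2,
    Dw3.
    """
    parts = []
    for locus_name in _LOCUS_ORDER:
        lg = g.loci.get(locus_name)
        if lg is None or lg.zygosity is None:
            raise InvalidInputError(
                f"cannot format genotype: locus {locus_name} call incomplete"
            )
        a, b = lg.allele_a.allele_name, lg.allele_b.allele_name
        if lg.zygosity == ZYG_HOM_WT:
            parts.append(locus_name)
        elif lg.zygosity == ZYG_HOM_MUT:
            parts.append(a)
        elif lg.zygosity == ZYG_HET:
            mutant = b if a == WILD_TYPE else a
            parts.append(locus_name + mutant)
        else:  # compound
            parts.append("/".join(sorted((a, b))))
    return "".join(parts)


def _mk_call(name: str) -> AlleleCall:
    return AlleleCall(name)


def parse_genotype_string(s: str) -> SampleGenotype:
    """Parse a genotype string back into per-locus diploid calls.

    Accepts both the single-token homozygous form used for inbred panels
    (``dw1Dw2dw3-ref``) and the doubled/heterozygous forms used for F2
    individuals (``Dw1dw1``, ``dw1dw1``); raises
    :class:`GenotypeParseError` with the offending position otherwise.
    """
    g = SampleGenotype(sample_id="", genotype_string=s)
    pos = 0
    for locus_name in _LOCUS_ORDER:
        wt_pat, mut_pat = _TOKEN_PATTERNS[locus_name]
        token_re = re.compile(f"(?:{wt_pat})|(?:{mut_pat})")

        m = token_re.match(s, pos)
        if m is None:
            raise GenotypeParseError(f"expected a {locus_name} token", pos)
        first = m.group(0)
        pos = m.end()

        second = None
        if pos < len(s) and s[pos] == "/":
            m2 = re.compile(mut_pat).match(s, pos + 1)
            if m2 is None or first[0] != "d":
                raise GenotypeParseError(
                    f"expected a second mutant {locus_name} allele after '/'", pos + 1
                )
            second = m2.group(0)
            pos = m2.end()
        else:
            m2 = token_re.match(s, pos)
            if m2 is not None:
                second = m2.group(0)
                pos = m2.end()

        def as_name(token: str) -> str:
            return WILD_TYPE if token[0] == "D" else token

        if second is None:
            a = b = as_name(first)  # single token: homozygous state
        else:
            a, b = as_name(first), as_name(second)
        g.loci[locus_name] = LocusGenotype(
            locus_name, _mk_call(a), _mk_call(b), _zygosity(a, b)
        )
    if pos != len(s):
        raise GenotypeParseError("trailing characters after Dw3 segment", pos)
    return g


def hom_mutant_loci(g: SampleGenotype) -> set[str]:
    """Locus names at which the sample is homozygous mutant."""
    return {
        name for name, lg in g.loci.items() if lg.zygosity == ZYG_HOM_MUT
    }


def mutant_alleles(g: SampleGenotype) -> set[str]:
    """All distinct mutant allele names present in the genotype."""
    out = set()
    for lg in g.loci.values():
        for call in (lg.allele_a, lg.allele_b):
            if call.allele_name not in (WILD_TYPE, UNKNOWN, None):
                out.add(call.allele_name)
    return out


# ---------------------------------------------------------------------------
# I/O

_HEADER_RE = re.compile(r"^(?P<sample>[^|]+)\|(?P<locus>Dw[123])(?:\|(?P<hap>hap[12]))?$")


def read_haplotype_fasta(path: str | Path) -> dict[str, dict[str, list[str]]]:
    """Read sample haplotypes from FASTA with headers
    ``SAMPLEID|LOCUS|hap1`` / ``...|hap2`` (the ``|hapN`` part optional for
    homozygous samples)."""
    panel: dict[str, dict[str, list[str]]] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        m = _HEADER_RE.match(record.id)
        if m is None:
            raise InvalidInputError(
                f"FASTA header {record.id!r} does not follow SAMPLE|LOCUS|hapN"
            )
        panel.setdefault(m["sample"], {}).setdefault(m["locus"], []).append(
            str(record.seq).upper()
        )
    return panel


def calls_to_dataframe(genotypes: Sequence[SampleGenotype]) -> pd.DataFrame:
    rows = []
    for g in genotypes:
        for locus_name, lg in g.loci.items():
            status = "ok" if lg.allele_a.ok and lg.allele_b.ok else "failed"
            rows.append(
                {
                    "sample_id": g.sample_id,
                    "locus": locus_name,
                    "allele_a": lg.allele_a.allele_name,
                    "allele_b": lg.allele_b.allele_name,
                    "zygosity": lg.zygosity,
                    "genotype_string": g.genotype_string,
                    "prescreen": lg.allele_a.prescreen,
                    "status": status,
                }
            )
    return pd.DataFrame(rows)
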