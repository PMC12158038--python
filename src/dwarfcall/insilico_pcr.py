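"""In-silico PCR: locate primer binding sites on a gene template and
extract the amplicon, plus the dw3 product-size prescreen.

Templates are stored gene-5'->3' with position 1 at the ATG start codon, so
only the forward strand is searched for the forward primer; the reverse
primer binds the bottom strand, i.e. its reverse complement is searched on
the stored strand downstream of the forward site.  The amplicon length
convention includes both primer footprints — the product size a gel would
show.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import reverse_complement

from .catalog import DNA_ALPHABET, Locus, PrimerPair
from .errors import AmbiguousPrimingError, InvalidInputError, NoSiteError

#: product classes returned by the dw3 size prescreen
INSERTION_CLASS = "insertion-class"
SHORT_CLASS = "short-class"

#: default dw3 size-prescreen threshold (bp).  Sits between the ~1280-bp
#: product of the point/short-indel alleles and the ~2.16-kb product of the
#: large-insertion allele, with several hundred bp of slack on either side.
DEFAULT_PRESCREEN_THRESHOLD = 1800

#: number of 3'-terminal primer bases that must match exactly when
#: mismatches are allowed elsewhere (mimics PCR extension specificity)
THREE_PRIME_ANCHOR = 3


@dataclass(frozen=True)
class Template:
    """A gene-length DNA sequence whose position 1 is the ATG start."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise InvalidInputError(f"template {self.id!r} is empty")
        if not set(self.sequence) <= DNA_ALPHABET:
            bad = sorted(set(self.sequence) - DNA_ALPHABET)
            raise InvalidInputError(f"template {self.id!r} has non-ACGT symbols {bad}")


@dataclass(frozen=True)
class Amplicon:
    """A PCR product with its 1-based inclusive template coordinates."""

    locus_name: str
    sequence: str
    template_start: int
    template_end: int

    @property
    def length(self) -> int:
        return len(self.sequence)


def _match_positions(
    haystack: str, needle: str, max_mismatch: int, anchor: str
) -> list[int]:
    """0-based start positions where ``needle`` matches ``haystack`` with at
    most ``max_mismatch`` mismatches and zero mismatches in the 3 bases at
    the ``anchor`` ("left"/"right") end."""
    n, m = len(haystack), len(needle)
    hits = []
    for start in range(n - m + 1):
        window = haystack[start : start + m]
        if max_mismatch == 0:
            if window == needle:
                hits.append(start)
            continue
        mismatches = sum(a != b for a, b in zip(window, needle))
        if mismatches > max_mismatch:
            continue
        if anchor == "right":
            anchored = window[-THREE_PRIME_ANCHOR:] == needle[-THREE_PRIME_ANCHOR:]
        else:
            anchored = window[:THREE_PRIME_ANCHOR] == needle[:THREE_PRIME_ANCHOR]
        if anchored:
            hits.append(start)
    return hits


def locate_primers(
    template: Template, primers: PrimerPair, max_mismatch: int = 0
) -> tuple[int, int]:
    """Find the unique productive binding sites of a primer pair.

    Returns 1-based start positions ``(forward_site, reverse_site)`` on the
    stored strand: ``forward_site`` is where the forward primer anneals and
    ``reverse_site`` where the reverse complement of the reverse primer
    begins, downstream of the forward site.

    Raises :class:`NoSiteError` if either primer has no productive site and
    :class:`AmbiguousPrimingError` if more than one product is possible.
    """
    if max_mismatch < 0:
        raise InvalidInputError("max_mismatch must be >= 0")
    seq = template.sequence
    fwd_hits = _match_positions(seq, primers.forward, max_mismatch, anchor="right")
    # the reverse primer's 3' end corresponds to the left edge of the
    # reverse-complement site on the stored strand
    rev_rc = reverse_complement(primers.reverse)
    rev_hits = _match_positions(seq, rev_rc, max_mismatch, anchor="left")
    if not fwd_hits:
        raise NoSiteError(f"forward primer has no site on template {template.id!r}")
    if not rev_hits:
        raise NoSiteError(f"reverse primer has no site on template {template.id!r}")
    products = [
        (f, r)
        for f in fwd_hits
        for r in rev_hits
        if r >= f + len(primers.forward)  # non-overlapping, reverse downstream
    ]
    if not products:
        raise NoSiteError(
            f"no productive primer orientation on template {template.id!r}"
        )
    if len(products) > 1:
        raise AmbiguousPrimingError(
            f"{len(products)} candidate products on template {template.id!r}"
        )
    f, r = products[0]
    return f + 1, r + 1


def amplify(template: Template, locus: Locus, max_mismatch: int = 0) -> Amplicon:
    """Extract the PCR product of ``locus``'s primer pair from ``template``.

    The product spans from the forward primer's 5' base through the base
    pairing the reverse primer's 5' base, inclusive.
    """
    fwd_site, rev_site = locate_primers(template, locus.primer_pair, max_mismatch)
    end = rev_site + len(reverse_complement(locus.primer_pair.reverse)) - 1
    return Amplicon(
        locus_name=locus.name,
        sequence=template.sequence[fwd_site - 1 : end],
        template_start=fwd_site,
        template_end=end,
    )


def dw3_size_prescreen(
    length: int, threshold: int = DEFAULT_PRESCREEN_THRESHOLD
) -> str:
    """Classify a dw3 product size as carrying the large insertion or not.

    The large-insertion allele yields a product ~0.9 kb longer than every
    other allele, so a single inclusive size threshold separates the two
    classes without sequencing.
    """
    if length <= 0:
        raise InvalidInputError("product length must be positive")
    return INSERTION_CLASS if length >= threshold else SHORT_CLASS


# ---------------------------------------------------------------------------
# FASTA I/O


def read_templates(path: str | Path) -> dict[str, Template]:
    """Read gene templates from FASTA; record id becomes the template id."""
    templates = {}
    for record in SeqIO.parse(str(path), "fasta"):
        templates[record.id] = Template(
            id=record.id,
            sequence=str(record.seq).upper(),
            description=record.description,
        )
    return templates


def write_templates(templates: dict[str, Template], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in templates.values():
            fh.write(f">{t.id}" + (f" {t.description}" if t.description else "") + "\n")
            for i in range(0, len(t.sequence), 70):
                fh.write(t.sequence[i : i + 70] + "\n")
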