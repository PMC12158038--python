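"""Fabricated reference genes, mutant haplotypes, landrace panels, and F2
populations for exercising the genotyping pipeline end to end.

The fabricated wild-type templates are seeded random DNA with the packaged
primer pairs embedded exactly once each, placed so that wild-type amplicon
lengths are exactly 427 (Dw1), 997 (Dw2), and 1280 bp (Dw3) and every
catalog signature interval lies inside its amplicon.  Bases flanking each
indel signature are constrained so that a left-normalized indel lands
exactly on its catalog coordinate (no ambiguous shifts).

The F2 simulator draws three unlinked loci segregating 1:2:1 from a selfed
triple heterozygote and assigns heights with an additive-plus-epistatic
Gaussian model; the packaged default effect model is calibrated so that the
noise-free genotype-class means equal the published single- and
double-recessive class means.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .catalog import AlleleCatalog, AlleleDefinition, default_catalog, lookup_allele
from .errors import InvalidInputError, InvalidSignatureError
from .insilico_pcr import Template, amplify

_BASES = np.array(list("ACGT"))

# template length and amplicon start per locus; ends follow from the
# wild-type amplicon lengths in the catalog
_PLACEMENTS = {
    "Dw1": {"template_length": 1900, "amplicon_start": 1100},
    "Dw2": {"template_length": 1600, "amplicon_start": 300},
    "Dw3": {"template_length": 7300, "amplicon_start": 5300},
}

# wild-type bases required at substitution / deletion signature sites
_FIXED_BASES = {
    "Dw1": {1350: "C"},  # the published wild-type base here is any non-T
    "Dw2": {549: "G", 550: "A"},
    "Dw3": {5406: "A", 5668: "A"},
}

#: per-locus homozygous mutant frequencies of the default landrace panel,
#: matching the carrier composition of the published sub-2-m survey table
#: relative to the 241-accession panel
DEFAULT_ALLELE_FREQUENCIES = {
    "dw1": 4 / 241,
    "dw2": 2 / 241,
    "dw3-ref": 11 / 241,
    "dw3-c": 4 / 241,
    "dw3-b": 1 / 241,
}

_PAIR_RE = re.compile(r"^(Dw\d)(Dw\d)$")


@dataclass(frozen=True)
class EffectModel:
    """Additive-plus-epistatic height model for recessive genotype classes.

    ``height = baseline - sum(single_effects[locus] for homozygous-recessive
    loci) - sum(epistasis[pair] for homozygous-recessive pairs) + N(0,
    residual_sd_cm)``.  Units are cm throughout.
    """

    baseline_cm: float
    single_effects: Mapping[str, float]
    epistasis: Mapping[str, float]
    residual_sd_cm: float

    def __post_init__(self):
        if self.residual_sd_cm < 0:
            raise InvalidInputError("residual_sd_cm must be >= 0")
        for key in self.epistasis:
            if _PAIR_RE.match(key) is None:
                raise InvalidInputError(f"epistasis key {key!r} is not a locus pair")

    def expected_height(self, hom_recessive: Mapping[str, bool]) -> float:
        height = self.baseline_cm
        for locus, effect in self.single_effects.items():
            if hom_recessive.get(locus, False):
                height -= effect
        for pair, effect in self.epistasis.items():
            l1, l2 = _PAIR_RE.match(pair).groups()
            if hom_recessive.get(l1, False) and hom_recessive.get(l2, False):
                height -= effect
        return height


def default_effect_model() -> EffectModel:
    """The packaged calibrated effect model (see data/effect_model.yaml)."""
    text = resources.files("dwarfcall.data").joinpath("effect_model.yaml").read_text()
    data = yaml.safe_load(text)
    return EffectModel(
        baseline_cm=float(data["baseline_cm"]),
        single_effects={k: float(v) for k, v in data["single_effects"].items()},
        epistasis={k: float(v) for k, v in data["epistasis"].items()},
        residual_sd_cm=float(data["residual_sd_cm"]),
    )


@dataclass
class SimulationConfig:
    seed: int
    n_accessions: int = 241
    allele_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ALLELE_FREQUENCIES)
    )
    effect_model: EffectModel | None = None
    sanger_error_rate: float = 0.0
    replicates: int = 3

    def __post_init__(self):
        if self.effect_model is None:
            self.effect_model = default_effect_model()
        for name, freq in self.allele_frequencies.items():
            if not 0.0 <= freq <= 1.0:
                raise InvalidInputError(f"frequency of {name!r} outside [0, 1]")


# ---------------------------------------------------------------------------
# Reference fabrication


def _random_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)].copy()


def _different_base(rng: np.random.Generator, *exclude: str) -> str:
    choices = [b for b in "ACGT" if b not in exclude]
    return choices[int(rng.integers(0, len(choices)))]


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def fabricate_references(
    seed: int, catalog: AlleleCatalog | None = None
) -> tuple[dict[str, Template], dict]:
    """Fabricate the three wild-type gene templates.

    Returns the templates keyed by locus name plus a placement report with
    amplicon coordinates.  The same seed always yields identical sequences.
    """
    if catalog is None:
        catalog = default_catalog()
    rng = np.random.default_rng(seed)
    templates: dict[str, Template] = {}
    report: dict = {}
    for locus in catalog.loci:
        placement = _PLACEMENTS[locus.name]
        amp_start = placement["amplicon_start"]
        amp_end = amp_start + locus.wild_type_amplicon_length - 1
        fwd = locus.primer_pair.forward
        rev_rc = _revcomp(locus.primer_pair.reverse)
        for _attempt in range(20):
            seq = _random_dna(rng, placement["template_length"])
            seq[0:3] = list("ATG")
            # primer footprints delimit the amplicon
            seq[amp_start - 1 : amp_start - 1 + len(fwd)] = list(fwd)
            seq[amp_end - len(rev_rc) : amp_end] = list(rev_rc)
            for pos, base in _FIXED_BASES[locus.name].items():
                seq[pos - 1] = base
            # anchor indel signatures: block left/right normalization shifts
            # so every indel's canonical placement is its catalog coordinate
            for allele in catalog.alleles_for(locus.name):
                sig = allele.signature
                if sig.kind == "deletion":
                    if seq[sig.start - 2] == seq[sig.end - 1]:
                        seq[sig.start - 2] = _different_base(rng, seq[sig.end - 1])
                    if seq[sig.end] == seq[sig.start - 1]:
                        seq[sig.end] = _different_base(rng, seq[sig.start - 1])
                elif sig.kind == "duplication":
                    if seq[sig.start - 2] == seq[sig.end - 1]:
                        seq[sig.start - 2] = _different_base(rng, seq[sig.end - 1])
            text = "".join(seq)
            if text.count(fwd) == 1 and text.count(rev_rc) == 1:
                break
        else:  # pragma: no cover - probability ~4^-20 per attempt
            raise RuntimeError("could not fabricate a template with unique primer sites")
        templates[locus.name] = Template(
            id=locus.name,
            sequence=text,
            description=f"fabricated synthetic wild-type {locus.gene_id}",
        )
        report[locus.name] = {
            "template_length": placement["template_length"],
            "amplicon_start": amp_start,
            "amplicon_end": amp_end,
            "amplicon_length": locus.wild_type_amplicon_length,
        }
    return templates, report


def apply_allele(
    template: Template, allele: AlleleDefinition, seed: int = 0
) -> Template:
    """Apply a mutation signature to a wild-type template.

    Substitutions replace the base; deletions remove the interval;
    insertions insert a seeded random sequence of the signature length
    (content is defined only when the catalog prints it); duplications
    insert a copy of the duplicated interval immediately after it.
    """
    sig = allele.signature
    seq = template.sequence
    if sig.start < 1 or sig.end > len(seq) + (1 if sig.kind == "insertion" else 0):
        raise InvalidSignatureError(
            f"signature {allele.allele_name} interval {sig.start}-{sig.end} "
            f"outside template of length {len(seq)}"
        )
    if sig.kind == "substitution":
        mutated = seq[: sig.start - 1] + sig.alt + seq[sig.start :]
    elif sig.kind == "deletion":
        mutated = seq[: sig.start - 1] + seq[sig.end :]
    elif sig.kind == "insertion":
        point = sig.start - 1  # inserted bases occupy positions start..end
        if sig.alt:
            ins = sig.alt
        else:
            rng = np.random.default_rng(seed)
            ins_arr = _random_dna(rng, sig.length)
            # pin the insert's ends so left/right normalization cannot move it
            if point >= 1 and ins_arr[-1] == seq[point - 1]:
                ins_arr[-1] = _different_base(rng, seq[point - 1])
            if point < len(seq) and ins_arr[0] == seq[point]:
                ins_arr[0] = _different_base(rng, seq[point])
            ins = "".join(ins_arr)
        mutated = seq[:point] + ins + seq[point:]
    elif sig.kind == "duplication":
        unit = seq[sig.start - 1 : sig.end]
        mutated = seq[: sig.end] + unit + seq[sig.end :]
    else:
        raise InvalidSignatureError(f"unknown signature kind {sig.kind!r}")
    return Template(
        id=f"{template.id}_{allele.allele_name}",
        sequence=mutated,
        description=f"{template.description} + {allele.allele_name}".strip(),
    )


def add_sanger_noise(
    sequence: str,
    error_rate: float,
    seed: int,
    protected_intervals: tuple[tuple[int, int], ...] = (),
) -> str:
    """Add seeded random substitution noise at ``error_rate`` outside the
    1-based inclusive ``protected_intervals``.  No indels are introduced."""
    if not 0.0 <= error_rate < 0.05:
        raise InvalidInputError("error_rate must be in [0, 0.05)")
    if error_rate == 0.0:
        return sequence
    rng = np.random.default_rng(seed)
    protected = np.zeros(len(sequence), dtype=bool)
    for start, end in protected_intervals:
        protected[max(start - 1, 0) : end] = True
    hits = np.flatnonzero((rng.random(len(sequence)) < error_rate) & ~protected)
    if hits.size == 0:
        return sequence
    seq = np.array(list(sequence))
    for i in hits:
        seq[i] = _different_base(rng, seq[i])
    return "".join(seq)


def protected_intervals_for(
    locus_name: str, catalog: AlleleCatalog, reference: Template
) -> tuple[tuple[int, int], ...]:
    """Intervals (1-based, wild-type coordinates) that substitution noise
    must not touch for calls to be invariant: both primer footprints and
    every signature interval with a one-base flank (the flank preserves the
    normalization anchors of indels)."""
    locus = catalog.locus(locus_name)
    amp = amplify(reference, locus)
    fwd_len = len(locus.primer_pair.forward)
    rev_len = len(locus.primer_pair.reverse)
    intervals = [
        (amp.template_start, amp.template_start + fwd_len - 1),
        (amp.template_end - rev_len + 1, amp.template_end),
    ]
    for allele in catalog.alleles_for(locus_name):
        sig = allele.signature
        if sig.kind == "insertion":
            intervals.append((sig.start - 1, sig.start))
        else:
            intervals.append((sig.start - 1, sig.end + 1))
    return tuple(intervals)


# ---------------------------------------------------------------------------
# Landrace panel simulation


@dataclass
class PanelResult:
    haplotypes: dict[str, dict[str, list[str]]]
    truth: pd.DataFrame
    phenotypes: pd.DataFrame


def simulate_landrace_panel(
    config: SimulationConfig,
    catalog: AlleleCatalog | None = None,
    references: Mapping[str, Template] | None = None,
) -> PanelResult:
    """Simulate an inbred landrace panel.

    Every accession is homozygous at all three loci; at each locus a mutant
    allele is drawn with its configured frequency (independently across
    loci), otherwise the accession is wild type there.  Heights follow the
    effect model with Gaussian residuals, one value per replicate.
    """
    if catalog is None:
        catalog = default_catalog()
    if references is None:
        references, _ = fabricate_references(config.seed, catalog)
    rng = np.random.default_rng(config.seed)
    model = config.effect_model

    per_locus: dict[str, tuple[list[str], np.ndarray]] = {}
    for locus_name in catalog.locus_names:
        names = [
            a.allele_name
            for a in catalog.alleles_for(locus_name)
            if config.allele_frequencies.get(a.allele_name, 0.0) > 0
        ]
        freqs = np.array([config.allele_frequencies[n] for n in names])
        if freqs.sum() > 1.0:
            raise InvalidInputError(f"{locus_name} mutant frequencies sum above 1")
        per_locus[locus_name] = (names, freqs)

    mutant_cache: dict[str, Template] = {}

    def mutant_template(locus_name: str, allele_name: str) -> Template:
        if allele_name not in mutant_cache:
            allele = lookup_allele(catalog, allele_name)
            mutant_cache[allele_name] = apply_allele(
                references[locus_name], allele, seed=config.seed
            )
        return mutant_cache[allele_name]

    haplotypes: dict[str, dict[str, list[str]]] = {}
    truth_rows = []
    pheno_rows = []
    for i in range(config.n_accessions):
        accession = f"SYN{i + 1:04d}"
        tokens = []
        hom: dict[str, bool] = {}
        haps: dict[str, list[str]] = {}
        for locus_name in catalog.locus_names:
            names, freqs = per_locus[locus_name]
            u = rng.random()
            chosen = None
            acc = 0.0
            for name, freq in zip(names, freqs):
                acc += freq
                if u < acc:
                    chosen = name
                    break
            hom[locus_name] = chosen is not None
            tokens.append(chosen if chosen else locus_name)
            base = (
                mutant_template(locus_name, chosen).sequence
                if chosen
                else references[locus_name].sequence
            )
            if config.sanger_error_rate > 0:
                base = add_sanger_noise(
                    base,
                    config.sanger_error_rate,
                    seed=int(rng.integers(0, 2**31)),
                    protected_intervals=protected_intervals_for(
                        locus_name, catalog, references[locus_name]
                    )
                    if not chosen
                    else (),
                )
            haps[locus_name] = [base]
        haplotypes[accession] = haps
        truth_rows.append({"accession_id": accession, "genotype": "".join(tokens)})
        genetic_value = model.expected_height(hom)
        for rep in range(1, config.replicates + 1):
            pheno_rows.append(
                {
                    "accession_id": accession,
                    "height_cm": genetic_value
                    + rng.normal(0.0, model.residual_sd_cm),
                    "replicate": rep,
                }
            )
    return PanelResult(
        haplotypes=haplotypes,
        truth=pd.DataFrame(truth_rows),
        phenotypes=pd.DataFrame(pheno_rows),
    )


def panel_to_fasta(panel: PanelResult, path: str | Path) -> None:
    """Write panel haplotypes in the caller's FASTA header grammar."""
    with open(path, "w") as fh:
        for accession, per_locus in panel.haplotypes.items():
            for locus_name, seqs in per_locus.items():
                for h, seq in enumerate(seqs, start=1):
                    fh.write(f">{accession}|{locus_name}|hap{h}\n")
                    for i in range(0, len(seq), 70):
                        fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# F2 population simulation


def simulate_f2(
    n: int,
    effect_model: EffectModel | None = None,
    seed: int = 0,
    dw3_allele: str = "dw3-ref",
) -> pd.DataFrame:
    """Simulate an F2 population from a selfed triple heterozygote.

    Three unlinked loci segregate independently; per locus the recessive
    allele dose is Binomial(2, 1/2), i.e. genotype probabilities 1/4 : 1/2 :
    1/4.  Heights come from the effect model.  Columns: ``individual, dw1,
    dw2, dw3`` (recessive allele dose), ``genotype_string, height_cm``.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if effect_model is None:
        effect_model = default_effect_model()
    rng = np.random.default_rng(seed)
    doses = rng.binomial(2, 0.5, size=(n, 3))
    mut_names = {"Dw1": "dw1", "Dw2": "dw2", "Dw3": dw3_allele}
    rows = []
    for i in range(n):
        hom = {
            locus: doses[i, j] == 2 for j, locus in enumerate(("Dw1", "Dw2", "Dw3"))
        }
        tokens = []
        for j, locus in enumerate(("Dw1", "Dw2", "Dw3")):
            dose = doses[i, j]
            if dose == 0:
                tokens.append(locus)
            elif dose == 1:
                tokens.append(locus + mut_names[locus])
            else:
                tokens.append(mut_names[locus])
        height = effect_model.expected_height(hom)
        if effect_model.residual_sd_cm > 0:
            height += rng.normal(0.0, effect_model.residual_sd_cm)
        rows.append(
            {
                "individual": f"F2_{i + 1:04d}",
                "dw1": int(doses[i, 0]),
                "dw2": int(doses[i, 1]),
                "dw3": int(doses[i, 2]),
                "genotype_string": "".join(tokens),
                "height_cm": height,
            }
        )
    return pd.DataFrame(rows)


def f2_haplotypes(
    table: pd.DataFrame,
    catalog: AlleleCatalog | None = None,
    references: Mapping[str, Template] | None = None,
    dw3_allele: str = "dw3-ref",
    seed: int = 0,
) -> dict[str, dict[str, list[str]]]:
    """Optional sequence-level view of an F2 table: two haplotype sequences
    per locus per individual (wild-type or mutant templates by dose)."""
    if catalog is None:
        catalog = default_catalog()
    if references is None:
        references, _ = fabricate_references(seed, catalog)
    mut_names = {"dw1": "dw1", "dw2": "dw2", "dw3": dw3_allele}
    mutants: dict[str, str] = {}
    for col, locus_name in (("dw1", "Dw1"), ("dw2", "Dw2"), ("dw3", "Dw3")):
        allele = lookup_allele(catalog, mut_names[col])
        mutants[col] = apply_allele(references[locus_name], allele, seed=seed).sequence
    out: dict[str, dict[str, list[str]]] = {}
    for _, row in table.iterrows():
        haps: dict[str, list[str]] = {}
        for col, locus_name in (("dw1", "Dw1"), ("dw2", "Dw2"), ("dw3", "Dw3")):
            dose = int(row[col])
            wt = references[locus_name].sequence
            mut = mutants[col]
            haps[locus_name] = [mut] * dose + [wt] * (2 - dose)
        out[str(row["individual"])] = haps
    return out
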