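import pytest

from dwarfcall.caller import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    UNKNOWN,
    WILD_TYPE,
    ZYG_COMPOUND,
    ZYG_HET,
    ZYG_HOM_MUT,
    ZYG_HOM_WT,
    Variant,
    align_amplicon,
    call_haplotype,
    call_sample,
    match_signatures,
    variants_from_alignment,
)
from dwarfcall.catalog import lookup_allele
from dwarfcall.errors import InvalidInputError
from dwarfcall.insilico_pcr import INSERTION_CLASS, SHORT_CLASS, Template, amplify
from dwarfcall.synthetic_data import (
    add_sanger_noise,
    apply_allele,
    protected_intervals_for,
)

# ---------------------------------------------------------------------------
# alignment and variant extraction


def test_align_identical_sequences_scores_match_reward():
    seq = "ACGT" * 25
    aln = align_amplicon(seq, seq, ref_offset=1)
    assert aln.query_aligned == aln.ref_aligned == seq
    assert aln.score == 2.0 * len(seq)
    assert variants_from_alignment(aln) == []


def test_align_two_base_deletion_yields_single_gap():
    ref = "ACGTACCATGGATCCTTGCA"
    qry = ref[:8] + ref[10:]  # drop "TG" at positions 9-10
    aln = align_amplicon(qry, ref, ref_offset=1)
    variants = variants_from_alignment(aln)
    assert len(variants) == 1
    v = variants[0]
    assert v.kind == DELETION and len(v.ref_allele) == 2


def test_align_single_substitution_single_mismatch_column():
    ref = "ACGTACCATGGATCCTTGCA"
    qry = ref[:5] + "G" + ref[6:]  # C>G at position 6
    aln = align_amplicon(qry, ref, ref_offset=1)
    variants = variants_from_alignment(aln)
    assert variants == [
        Variant(position=6, kind=SUBSTITUTION, ref_allele="C", alt_allele="G")
    ]


def test_align_rejects_empty_input():
    with pytest.raises(InvalidInputError):
        align_amplicon("", "ACGT", ref_offset=1)


def test_deletion_in_repeat_is_left_normalized():
    ref = "CCGTAAAATGCC"
    qry = "CCGTAAATGCC"  # one A removed from the AAAA run
    aln = align_amplicon(qry, ref, ref_offset=1)
    (v,) = variants_from_alignment(aln)
    assert v == Variant(position=5, kind=DELETION, ref_allele="A")


def test_insertion_in_repeat_is_left_normalized():
    ref = "CCGTAAAATGCC"
    qry = "CCGTAAAAATGCC"  # one A added to the AAAA run
    aln = align_amplicon(qry, ref, ref_offset=1)
    (v,) = variants_from_alignment(aln)
    assert v == Variant(position=5, kind=INSERTION, alt_allele="A")


def test_ref_offset_shifts_variant_positions():
    ref = "ACGTACCATGGATCCTTGCA"
    qry = ref[:5] + "G" + ref[6:]
    aln = align_amplicon(qry, ref, ref_offset=1001)
    (v,) = variants_from_alignment(aln)
    assert v.position == 1006


def test_catalog_deletion_variant_extracted_at_signature_coordinates(
    catalog, references
):
    """The dw3-c haplotype aligns to one 2-bp deletion at 5967."""
    mutant = apply_allele(references["Dw3"], lookup_allele(catalog, "dw3-c"))
    locus = catalog.locus("Dw3")
    ref_amp = amplify(references["Dw3"], locus)
    mut_amp = amplify(mutant, locus)
    aln = align_amplicon(mut_amp.sequence, ref_amp.sequence, ref_amp.template_start)
    (v,) = variants_from_alignment(aln)
    assert v.kind == DELETION and v.position == 5967 and len(v.ref_allele) == 2


def test_large_insertion_variant_extracted_at_signature_coordinates(
    catalog, references
):
    mutant = apply_allele(references["Dw3"], lookup_allele(catalog, "dw3-ref"))
    locus = catalog.locus("Dw3")
    ref_amp = amplify(references["Dw3"], locus)
    mut_amp = amplify(mutant, locus)
    aln = align_amplicon(mut_amp.sequence, ref_amp.sequence, ref_amp.template_start)
    (v,) = variants_from_alignment(aln)
    assert v.kind == INSERTION and v.position == 6204 and len(v.alt_allele) == 882


# ---------------------------------------------------------------------------
# signature matching


def test_match_thymine_at_1350_is_dw1(catalog):
    variants = [Variant(1350, SUBSTITUTION, ref_allele="C", alt_allele="T")]
    assert match_signatures(variants, catalog, "Dw1").allele_name == "dw1"


def test_match_no_variants_is_wild_type(catalog):
    assert match_signatures([], catalog, "Dw3").allele_name == WILD_TYPE


def test_match_a_to_c_at_5406_is_dw3a(catalog):
    variants = [Variant(5406, SUBSTITUTION, ref_allele="A", alt_allele="C")]
    assert match_signatures(variants, catalog, "Dw3").allele_name == "dw3-a"


def test_match_wrong_alt_base_is_unknown(catalog):
    variants = [Variant(5406, SUBSTITUTION, ref_allele="A", alt_allele="T")]
    assert match_signatures(variants, catalog, "Dw3").allele_name == UNKNOWN


def test_match_two_signatures_is_unknown_not_arbitrary(catalog):
    variants = [
        Variant(5406, SUBSTITUTION, ref_allele="A", alt_allele="C"),
        Variant(5668, SUBSTITUTION, ref_allele="A", alt_allele="G"),
    ]
    call = match_signatures(variants, catalog, "Dw3")
    assert call.allele_name == UNKNOWN
    assert "multiple" in call.reason


def test_match_noise_variant_away_from_signatures_is_ignored(catalog):
    variants = [Variant(5500 - 100, SUBSTITUTION, ref_allele="A", alt_allele="G")]
    assert match_signatures(variants, catalog, "Dw3").allele_name == WILD_TYPE


# ---------------------------------------------------------------------------
# haplotype round trip — the module's primary oracle


def test_wild_type_haplotypes_call_wild_type(catalog, references):
    for locus in catalog.loci:
        call = call_haplotype(
            references[locus.name].sequence, locus, catalog, references[locus.name]
        )
        assert call.allele_name == WILD_TYPE


@pytest.mark.parametrize(
    "allele_name",
    ["dw1", "dw2", "dw3-ref", "dw3-a", "dw3-b", "dw3-c", "dw3-sd3", "dw3-sd4", "dw3-sd5"],
)
def test_apply_then_call_recovers_every_allele(catalog, references, allele_name):
    allele = lookup_allele(catalog, allele_name)
    locus = catalog.locus(allele.locus_name)
    mutant = apply_allele(references[allele.locus_name], allele, seed=7)
    call = call_haplotype(mutant.sequence, locus, catalog, references[allele.locus_name])
    assert call.allele_name == allele_name
    if locus.name == "Dw3":
        expected = INSERTION_CLASS if allele_name == "dw3-ref" else SHORT_CLASS
        assert call.prescreen == expected


@pytest.mark.parametrize(
    "allele_name",
    ["dw1", "dw2", "dw3-ref", "dw3-a", "dw3-b", "dw3-c", "dw3-sd3", "dw3-sd4", "dw3-sd5"],
)
def test_calls_unchanged_under_sequencing_noise(catalog, references, allele_name):
    """0.2% substitution noise outside signature sites leaves every call
    unchanged."""
    allele = lookup_allele(catalog, allele_name)
    locus = catalog.locus(allele.locus_name)
    ref = references[allele.locus_name]
    noisy = Template(
        id=ref.id,
        sequence=add_sanger_noise(
            ref.sequence,
            0.002,
            seed=1234,
            protected_intervals=protected_intervals_for(locus.name, catalog, ref),
        ),
    )
    mutant = apply_allele(noisy, allele, seed=7)
    call = call_haplotype(mutant.sequence, locus, catalog, ref)
    assert call.allele_name == allele_name


def test_failed_amplification_reports_reason(catalog, references):
    call = call_haplotype("ACGT" * 100, catalog.locus("Dw1"), catalog, references["Dw1"])
    assert call.status == "failed"
    assert "primer" in call.reason


# ---------------------------------------------------------------------------
# diploid sample calls


def _haps(catalog, references, spec):
    """spec: locus -> (allele_or_None, allele_or_None)."""
    out = {}
    for locus_name, pair in spec.items():
        seqs = []
        for name in pair:
            if name is None:
                seqs.append(references[locus_name].sequence)
            else:
                seqs.append(
                    apply_allele(
                        references[locus_name], lookup_allele(catalog, name), seed=7
                    ).sequence
                )
        out[locus_name] = seqs
    return out


def test_homozygous_mutant_sample(catalog, references):
    haps = _haps(
        catalog,
        references,
        {"Dw1": ("dw1", "dw1"), "Dw2": (None, None), "Dw3": (None, None)},
    )
    g = call_sample("s1", haps, catalog, references)
    assert g.loci["Dw1"].zygosity == ZYG_HOM_MUT
    assert g.loci["Dw2"].zygosity == ZYG_HOM_WT
    assert g.genotype_string == "dw1Dw2Dw3"


def test_heterozygous_sample(catalog, references):
    haps = _haps(
        catalog,
        references,
        {"Dw1": (None, "dw1"), "Dw2": (None, None), "Dw3": (None, None)},
    )
    g = call_sample("s2", haps, catalog, references)
    assert g.loci["Dw1"].zygosity == ZYG_HET
    assert g.genotype_string.startswith("Dw1dw1")


def test_compound_heterozygous_dw3(catalog, references):
    haps = _haps(
        catalog,
        references,
        {"Dw1": (None, None), "Dw2": (None, None), "Dw3": ("dw3-a", "dw3-b")},
    )
    g = call_sample("s3", haps, catalog, references)
    assert g.loci["Dw3"].zygosity == ZYG_COMPOUND
    assert "dw3-a/dw3-b" in g.genotype_string


def test_single_haplotype_treated_as_homozygous(catalog, references):
    mutant = apply_allele(references["Dw2"], lookup_allele(catalog, "dw2"), seed=7)
    haps = {
        "Dw1": [references["Dw1"].sequence],
        "Dw2": [mutant.sequence],
        "Dw3": [references["Dw3"].sequence],
    }
    g = call_sample("s4", haps, catalog, references)
    assert g.genotype_string == "Dw1dw2Dw3"


def test_missing_locus_fails_only_that_locus(catalog, references):
    haps = {
        "Dw1": [references["Dw1"].sequence],
        "Dw3": [references["Dw3"].sequence],
    }
    g = call_sample("s5", haps, catalog, references)
    assert g.loci["Dw2"].allele_a.status == "failed"
    assert g.loci["Dw1"].zygosity == ZYG_HOM_WT
    assert g.loci["Dw3"].zygosity == ZYG_HOM_WT
    assert g.genotype_string == ""
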