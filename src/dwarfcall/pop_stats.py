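"""Population-level analyses: landrace survey summaries, F2 genotype-class
height comparisons, Welch t-tests, and broad-sense heritability.

The survey summary counts carriers of the recessive dwarfing alleles in a
genotyped panel (a carrier is an accession homozygous mutant at one or more
of Dw1-Dw3) and bins plant heights into 50-cm classes.  F2 analyses group
individuals by single- and pairwise-recessive genotype classes and compare
class mean heights.  Broad-sense heritability H2 = VG/VP is estimated from
balanced replicated phenotype records via one-way random-effects ANOVA
variance components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .caller import ZYG_HOM_MUT, hom_mutant_loci, mutant_alleles, parse_genotype_string
from .errors import DegenerateInputError, InvalidInputError, UnsupportedDesignError

DEFAULT_HEIGHT_THRESHOLD_CM = 200.0

SINGLE_GROUPS = ("dw1", "dw2", "dw3")
PAIR_GROUPS = ("dw1dw2", "dw1dw3", "dw2dw3")

_GROUP_LOCI = {
    "dw1": ("Dw1",),
    "dw2": ("Dw2",),
    "dw3": ("Dw3",),
    "dw1dw2": ("Dw1", "Dw2"),
    "dw1dw3": ("Dw1", "Dw3"),
    "dw2dw3": ("Dw2", "Dw3"),
}


@dataclass(frozen=True)
class PhenotypeRecord:
    accession_id: str
    height_cm: float
    replicate: int

    def __post_init__(self):
        if self.height_cm <= 0:
            raise InvalidInputError(
                f"height must be positive, got {self.height_cm} for {self.accession_id}"
            )


@dataclass
class HistogramResult:
    """Counts per 50-cm height class; class k covers ((k-1)*w, k*w]."""

    bin_width: float
    counts: np.ndarray
    percents: np.ndarray
    out_of_range: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class SurveySummary:
    n_total: int
    n_below_threshold: int
    n_carriers: int
    n_carriers_by_locus: dict[str, int]
    n_carriers_by_allele: dict[str, int]
    carrier_percent: float
    histogram: HistogramResult


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean_cm: float
    sd_cm: float


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float


@dataclass(frozen=True)
class HeritabilityResult:
    VG: float
    VE: float
    VP: float
    H2: float
    replicates_per_accession: int


def height_histogram(
    heights: Iterable[float], bin_width: float = 50.0, bin_max: float = 400.0
) -> HistogramResult:
    """Bin heights into classes ((k-1)*bin_width, k*bin_width], k=1..K.

    Heights outside (0, bin_max] are reported in ``out_of_range`` rather
    than silently dropped.
    """
    n_bins = int(round(bin_max / bin_width))
    counts = np.zeros(n_bins, dtype=int)
    out_of_range = []
    for h in heights:
        if h <= 0 or h > bin_max:
            out_of_range.append(h)
            continue
        k = int(np.ceil(h / bin_width))
        counts[k - 1] += 1
    total = counts.sum()
    percents = 100.0 * counts / total if total else np.zeros(n_bins)
    return HistogramResult(bin_width, counts, percents, out_of_range)


def summarize_survey(
    genotypes: Mapping[str, str],
    phenotypes: Mapping[str, float],
    n_total: int,
    threshold_cm: float = DEFAULT_HEIGHT_THRESHOLD_CM,
) -> SurveySummary:
    """Summarise a genotyped landrace panel.

    ``genotypes`` maps accession to genotype string (inbred single-token
    form), ``phenotypes`` maps accession to mean height; ``n_total`` is the
    full panel size (accessions not listed are assumed wild type and above
    the height threshold, matching the usual reporting layout in which only
    short accessions are genotyped in detail).
    """
    by_locus: dict[str, int] = {"Dw1": 0, "Dw2": 0, "Dw3": 0}
    by_allele: dict[str, int] = {}
    n_carriers = 0
    for accession, gstring in genotypes.items():
        try:
            g = parse_genotype_string(gstring)
        except Exception as exc:
            raise InvalidInputError(
                f"accession {accession!r}: cannot parse genotype {gstring!r}: {exc}"
            ) from exc
        hom = hom_mutant_loci(g)
        if hom:
            n_carriers += 1
            for locus in hom:
                by_locus[locus] += 1
            for allele in mutant_alleles(g):
                by_allele[allele] = by_allele.get(allele, 0) + 1
    heights = list(phenotypes.values())
    n_below = sum(h < threshold_cm for h in heights)
    return SurveySummary(
        n_total=n_total,
        n_below_threshold=n_below,
        n_carriers=n_carriers,
        n_carriers_by_locus=by_locus,
        n_carriers_by_allele=by_allele,
        carrier_percent=100.0 * n_carriers / n_total,
        histogram=height_histogram(heights),
    )


def max_carrier_height(
    genotypes: Mapping[str, str],
    phenotypes: Mapping[str, float],
    exclude: Sequence[str] = (),
) -> float:
    """Maximum mean height among carrier accessions, optionally excluding
    named outliers."""
    heights = []
    for accession, gstring in genotypes.items():
        if accession in exclude:
            continue
        if hom_mutant_loci(parse_genotype_string(gstring)):
            heights.append(phenotypes[accession])
    if not heights:
        raise DegenerateInputError("no carrier accessions")
    return max(heights)


# ---------------------------------------------------------------------------
# F2 genotype-class analysis


def _hom_flags(f2_genotypes) -> pd.DataFrame:
    """Normalise F2 genotype input to a boolean homozygous-recessive matrix
    with columns Dw1, Dw2, Dw3.

    Accepts a DataFrame with columns ``dw1, dw2, dw3`` holding recessive
    allele counts (0/1/2), or a mapping individual -> SampleGenotype.
    """
    if isinstance(f2_genotypes, pd.DataFrame):
        missing = [c for c in ("dw1", "dw2", "dw3") if c not in f2_genotypes.columns]
        if missing:
            raise InvalidInputError(f"F2 table lacks columns {missing}")
        return pd.DataFrame(
            {
                "Dw1": f2_genotypes["dw1"] == 2,
                "Dw2": f2_genotypes["dw2"] == 2,
                "Dw3": f2_genotypes["dw3"] == 2,
            },
            index=f2_genotypes.index,
        )
    rows = {}
    for individual, g in f2_genotypes.items():
        hom = {
            name: lg.zygosity == ZYG_HOM_MUT for name, lg in g.loci.items()
        }
        rows[individual] = [hom.get("Dw1", False), hom.get("Dw2", False), hom.get("Dw3", False)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=["Dw1", "Dw2", "Dw3"])


def group_f2(f2_genotypes, mode: str = "exclusive") -> dict[str, pd.Index]:
    """Assign F2 individuals to single- and pairwise-recessive groups.

    In ``exclusive`` mode (default) a single-locus group contains
    individuals homozygous recessive at that locus and at no other, and a
    pairwise group those homozygous recessive at exactly that pair;
    ``inclusive`` mode drops the exclusion of the remaining loci.
    Heterozygotes never count as mutant.  In exclusive mode the six groups
    are pairwise disjoint.
    """
    if mode not in ("exclusive", "inclusive"):
        raise InvalidInputError(f"unknown grouping mode {mode!r}")
    hom = _hom_flags(f2_genotypes)
    groups: dict[str, pd.Index] = {}
    all_loci = ("Dw1", "Dw2", "Dw3")
    for label, loci in _GROUP_LOCI.items():
        mask = np.ones(len(hom), dtype=bool)
        for locus in loci:
            mask &= hom[locus].to_numpy()
        if mode == "exclusive":
            for locus in all_loci:
                if locus not in loci:
                    mask &= ~hom[locus].to_numpy()
        groups[label] = hom.index[mask]
    return groups


def group_summary(label: str, heights: Sequence[float]) -> GroupSummary:
    """Mean and sample standard deviation (n-1 denominator) of a group."""
    arr = np.asarray(list(heights), dtype=float)
    if arr.size == 0:
        raise DegenerateInputError(f"group {label!r} is empty")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return GroupSummary(label=label, n=int(arr.size), mean_cm=float(arr.mean()), sd_cm=sd)


def welch_t_test(
    a: Sequence[float], b: Sequence[float], pooled: bool = False
) -> TTestResult:
    """Two-sided t-test for a difference in group means.

    Defaults to the Welch unequal-variance form with Welch-Satterthwaite
    degrees of freedom; ``pooled=True`` gives the classical pooled-variance
    Student test.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("each group needs n >= 2")
    # constant groups make the statistic undefined; np.var of a constant
    # array can return ~1e-28 from cancellation, so test the range instead
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise DegenerateInputError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=pooled)
    return TTestResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
    )


def analyze_f2(
    table: pd.DataFrame, mode: str = "exclusive", bonferroni: bool = False
) -> tuple[list[GroupSummary], dict[str, TTestResult]]:
    """Group an F2 genotype/height table and compare the pairwise classes.

    Returns the six group summaries and the three t-tests between pairwise
    recessive classes.  ``bonferroni=True`` multiplies those p-values by 3
    (capped at 1); by default no multiple-testing correction is applied.
    """
    groups = group_f2(table, mode)
    summaries = []
    for label in SINGLE_GROUPS + PAIR_GROUPS:
        idx = groups[label]
        if len(idx) == 0:
            continue
        summaries.append(group_summary(label, table.loc[idx, "height_cm"]))
    tests = {}
    pairs = [("dw1dw2", "dw1dw3"), ("dw1dw2", "dw2dw3"), ("dw1dw3", "dw2dw3")]
    for g1, g2 in pairs:
        i1, i2 = groups[g1], groups[g2]
        if len(i1) < 2 or len(i2) < 2:
            continue
        try:
            res = welch_t_test(table.loc[i1, "height_cm"], table.loc[i2, "height_cm"])
        except DegenerateInputError:
            continue
        if bonferroni:
            res = TTestResult(
                res.t_statistic, res.degrees_of_freedom, min(1.0, 3 * res.p_value)
            )
        tests[f"{g1}_vs_{g2}"] = res
    return summaries, tests


# ---------------------------------------------------------------------------
# Broad-sense heritability


def broad_sense_H2(records) -> HeritabilityResult:
    """Estimate broad-sense heritability H2 = VG/VP from a balanced
    replicated panel.

    ``records`` is a DataFrame with columns ``accession_id, height_cm,
    replicate`` or an iterable of :class:`PhenotypeRecord`.  With a one-way
    random-effects layout and r replicates per accession, the ANOVA mean
    squares give VE = MS_within and VG = (MS_between - MS_within) / r
    (clipped at zero); VP = VG + VE.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(
            [
                {"accession_id": r.accession_id, "height_cm": r.height_cm, "replicate": r.replicate}
                for r in records
            ]
        )
    counts = records.groupby("accession_id")["height_cm"].count()
    if len(counts) < 2:
        raise UnsupportedDesignError("need at least two accessions")
    if counts.nunique() != 1:
        raise UnsupportedDesignError("unbalanced design: unequal replicate counts")
    r = int(counts.iloc[0])
    if r < 2:
        raise UnsupportedDesignError("need at least two replicates per accession")
    y = records["height_cm"].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        raise DegenerateInputError("all observations identical: VP = 0")
    group_means = records.groupby("accession_id")["height_cm"].mean()
    grand = y.mean()
    a = len(group_means)
    ss_between = r * float(((group_means - grand) ** 2).sum())
    ms_between = ss_between / (a - 1)
    resid = records["height_cm"] - records["accession_id"].map(group_means)
    ss_within = float((resid**2).sum())
    ms_within = ss_within / (a * (r - 1))
    VE = ms_within
    VG = max((ms_between - ms_within) / r, 0.0)
    VP = VG + VE
    if VP == 0:
        raise DegenerateInputError("phenotypic variance is zero")
    H2 = min(max(VG / VP, 0.0), 1.0)
    return HeritabilityResult(VG=VG, VE=VE, VP=VP, H2=H2, replicates_per_accession=r)


# ---------------------------------------------------------------------------
# Packaged survey data


def load_table1() -> pd.DataFrame:
    """Packaged transcription of the published sub-2-m landrace table:
    30 accessions with genotype string, mean height, and SD."""
    with resources.files("dwarfcall.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)


def load_table2() -> pd.DataFrame:
    """Packaged transcription of the two cross parents."""
    with resources.files("dwarfcall.data").joinpath("table2.csv").open() as fh:
        return pd.read_csv(fh)
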