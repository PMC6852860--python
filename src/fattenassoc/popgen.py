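"""Population-genetic characterization of biallelic SNP markers.

Allele and genotype frequencies, a Pearson chi-square test of
Hardy-Weinberg equilibrium, and the classical marker-informativeness
indices of Botstein et al.: expected homozygosity (Ho), expected
heterozygosity (He), effective allele number (Ne) and polymorphism
information content (PIC).

Two computational conventions coexist here and both are exposed:

* the HWE chi-square is computed from *exact* count-derived allele
  frequencies (anything else distorts the statistic);
* the diversity indices are, by default in the summary path, computed
  from allele frequencies rounded to the precision at which such
  frequencies are conventionally reported (2 decimals).  Published
  index tables for this kind of marker panel are produced from the
  reported frequencies, and the package reproduces that convention;
  pass ``freq_decimals=None`` to use exact frequencies instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeCounts",
    "AlleleFrequencies",
    "DiversityIndices",
    "HweResult",
    "MonomorphicMarkerError",
    "UnknownAlleleError",
    "count_genotypes",
    "allele_frequencies",
    "diversity_indices",
    "hwe_test",
    "significance_stars",
    "normalize_genotype",
    "summarize_markers",
]


class UnknownAlleleError(ValueError):
    """A genotype call contains a symbol outside the marker's two alleles."""


class MonomorphicMarkerError(ValueError):
    """The HWE test is undefined for a marker with a single observed allele."""


def normalize_genotype(call: str) -> str:
    """Return the genotype with allele symbols in lexical order ('TC' -> 'CT')."""
    return "".join(sorted(call))


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype tallies for one biallelic marker in a cohort.

    ``counts`` is ordered (hom_first, het, hom_second) where *first* is the
    lexically smaller allele symbol.
    """

    marker: str
    alleles: tuple[str, str]
    counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError(f"negative genotype count for marker {self.marker!r}")
        if self.n < 1:
            raise ValueError(f"empty cohort for marker {self.marker!r}")

    @property
    def n(self) -> int:
        return int(sum(self.counts))

    @property
    def genotype_labels(self) -> tuple[str, str, str]:
        a, b = self.alleles
        return (a + a, "".join(sorted(a + b)), b + b)


@dataclass(frozen=True)
class AlleleFrequencies:
    """Allele frequencies p_i for one marker, summing to 1."""

    alleles: tuple[str, ...]
    freqs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) != len(self.freqs):
            raise ValueError("alleles and freqs must align")
        if any(not (0.0 <= p <= 1.0) for p in self.freqs):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if abs(sum(self.freqs) - 1.0) > 1e-12:
            raise ValueError("allele frequencies must sum to 1")

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    @property
    def maf(self) -> float:
        return float(min(self.freqs))

    def rounded(self, decimals: int) -> "AlleleFrequencies":
        """Frequencies at reporting precision, renormalized onto the first allele.

        For a biallelic marker rounding both p and q=1-p to the same number
        of decimals keeps their sum at 1; the renormalization matters only
        for multi-allelic inputs.
        """
        r = np.round(self.freqs, decimals)
        r[0] += 1.0 - r.sum()
        return AlleleFrequencies(self.alleles, tuple(float(x) for x in r))


@dataclass(frozen=True)
class DiversityIndices:
    """Botstein-style marker informativeness indices."""

    ho: float  # expected homozygosity, sum p_i^2
    he: float  # expected heterozygosity, 1 - sum p_i^2
    ne: float  # effective allele number, 1 / sum p_i^2
    pic: float  # polymorphism information content
    maf: float


@dataclass(frozen=True)
class HweResult:
    """Pearson chi-square test of Hardy-Weinberg genotype proportions."""

    chi2: float
    df: int
    p_value: float
    expected_counts: tuple[float, float, float]


def count_genotypes(
    calls: Iterable[str], alleles: Sequence[str], marker: str = ""
) -> GenotypeCounts:
    """Tally genotype calls into (hom_first, het, hom_second).

    Heterozygotes are recognized irrespective of the written allele order
    ('CT' and 'TC' are the same genotype).  A call using a symbol outside
    the marker's two alleles raises :class:`UnknownAlleleError`.
    """
    a, b = sorted(alleles)
    hom_first, het, hom_second = a + a, a + b, b + b
    tally = {hom_first: 0, het: 0, hom_second: 0}
    for i, call in enumerate(calls):
        g = normalize_genotype(str(call))
        if g not in tally:
            raise UnknownAlleleError(
                f"call {call!r} (record {i}) uses an allele outside "
                f"{a}/{b} for marker {marker!r}"
            )
        tally[g] += 1
    return GenotypeCounts(
        marker=marker,
        alleles=(a, b),
        counts=(tally[hom_first], tally[het], tally[hom_second]),
    )


def allele_frequencies(counts: GenotypeCounts) -> AlleleFrequencies:
    """Count-derived allele frequencies: p_first = (2*hom_first + het) / 2n."""
    n11, n12, n22 = counts.counts
    two_n = 2 * counts.n
    p = (2 * n11 + n12) / two_n
    return AlleleFrequencies(counts.alleles, (p, 1.0 - p))


def diversity_indices(
    freqs: AlleleFrequencies, freq_decimals: int | None = None
) -> DiversityIndices:
    """Ho, He, Ne and PIC from a vector of allele frequencies.

    Ho = sum p_i^2;  He = 1 - Ho;  Ne = 1/Ho;
    PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2.

    ``freq_decimals`` rounds the frequencies to reporting precision first
    (see module docstring); ``None`` uses them as given.
    """
    if freq_decimals is not None:
        freqs = freqs.rounded(freq_decimals)
    p = np.asarray(freqs.freqs, dtype=float)
    ho = float(np.sum(p**2))
    he = 1.0 - ho
    ne = 1.0 / ho
    p2 = p**2
    cross = (np.sum(p2) ** 2 - np.sum(p2**2)) / 2.0  # sum_{i<j} p_i^2 p_j^2
    pic = he - 2.0 * cross
    return DiversityIndices(ho=ho, he=he, ne=ne, pic=pic, maf=freqs.maf)


def hwe_test(counts: GenotypeCounts) -> HweResult:
    """Pearson chi-square of observed genotype counts against n*(p^2, 2pq, q^2).

    Uses exact count-derived allele frequencies, no continuity correction,
    df = 3 genotype classes - 2 alleles = 1.  A genotype class observed zero
    times still contributes (0 - E)^2 / E.  Monomorphic markers have an
    expected-zero class and the statistic is undefined:
    :class:`MonomorphicMarkerError` is raised.
    """
    freqs = allele_frequencies(counts)
    p, q = freqs.freqs
    if p == 0.0 or q == 0.0:
        raise MonomorphicMarkerError(
            f"marker {counts.marker!r} is monomorphic; the HWE test is undefined"
        )
    n = counts.n
    expected = (n * p * p, n * 2 * p * q, n * q * q)
    observed = counts.counts
    chi2 = float(sum((o - e) ** 2 / e for o, e in zip(observed, expected)))
    df = 1
    p_value = float(stats.chi2.sf(chi2, df))
    return HweResult(chi2=chi2, df=df, p_value=p_value, expected_counts=expected)


def significance_stars(p: float, levels: tuple[float, ...] = (0.05, 0.01, 0.001)) -> str:
    """'*' for p<0.05, '**' for p<0.01, '***' for p<0.001; '' otherwise."""
    return "*" * sum(p < level for level in levels)


def summarize_markers(
    genotypes: pd.DataFrame,
    marker_alleles: dict[str, Sequence[str]] | None = None,
    freq_decimals: int | None = 2,
) -> pd.DataFrame:
    """Per-marker population-genetic summary from a long genotype table.

    Parameters
    ----------
    genotypes
        Long table with columns ``marker`` and ``genotype`` (one row per
        animal x marker; an ``animal_id`` column is allowed and ignored).
    marker_alleles
        Optional mapping marker -> pair of allele symbols.  By default the
        alleles are inferred from the observed calls; supplying the map is
        required when a marker is observed monomorphic but known biallelic.
    freq_decimals
        Reporting precision applied to allele frequencies before the
        diversity indices are computed (the HWE test always uses exact
        frequencies).  ``None`` disables rounding.

    Returns one row per marker with frequencies, genotype counts, the HWE
    chi-square test and the diversity indices.
    """
    rows = []
    for marker, sub in genotypes.groupby("marker", sort=True):
        calls = sub["genotype"].astype(str).tolist()
        if marker_alleles and marker in marker_alleles:
            alleles = tuple(marker_alleles[marker])
        else:
            alleles = tuple(sorted({a for c in calls for a in c}))
            if len(alleles) == 1:
                alleles = (alleles[0], alleles[0])
        counts = count_genotypes(calls, alleles, marker=str(marker))
        freqs = allele_frequencies(counts)
        div = diversity_indices(freqs, freq_decimals=freq_decimals)
        try:
            hwe = hwe_test(counts)
            chi2, p_hwe = hwe.chi2, hwe.p_value
        except MonomorphicMarkerError:
            chi2, p_hwe = np.nan, np.nan
        a, b = counts.alleles
        rows.append(
            {
                "marker": marker,
                "n": counts.n,
                "allele_first": a,
                "allele_second": b,
                "freq_first": freqs.freqs[0],
                "freq_second": freqs.freqs[1],
                "n_hom_first": counts.counts[0],
                "n_het": counts.counts[1],
                "n_hom_second": counts.counts[2],
                "chi2_hwe": chi2,
                "df_hwe": 1,
                "p_hwe": p_hwe,
                "hwe_stars": significance_stars(p_hwe) if np.isfinite(p_hwe) else "",
                "Ho": div.ho,
                "He": div.he,
                "Ne": div.ne,
                "PIC": div.pic,
                "MAF": div.maf,
            }
        )
    return pd.DataFrame(rows)


def summary_from_counts(
    counts_table: pd.DataFrame, freq_decimals: int | None = 2
) -> pd.DataFrame:
    """Population-genetic summary from a table of pre-tallied genotype counts.

    Expects columns marker, allele_first, allele_second, n_hom_first,
    n_het, n_hom_second (the layout of the packaged reference dataset).
    """
    rows = []
    for rec in counts_table.to_dict("records"):
        counts = GenotypeCounts(
            marker=str(rec["marker"]),
            alleles=(str(rec["allele_first"]), str(rec["allele_second"])),
            counts=(int(rec["n_hom_first"]), int(rec["n_het"]), int(rec["n_hom_second"])),
        )
        freqs = allele_frequencies(counts)
        div = diversity_indices(freqs, freq_decimals=freq_decimals)
        hwe = hwe_test(counts)
        rows.append(
            {
                "marker": counts.marker,
                "n": counts.n,
                "allele_first": counts.alleles[0],
                "allele_second": counts.alleles[1],
                "freq_first": freqs.freqs[0],
                "freq_second": freqs.freqs[1],
                "n_hom_first": counts.counts[0],
                "n_het": counts.counts[1],
                "n_hom_second": counts.counts[2],
                "chi2_hwe": hwe.chi2,
                "df_hwe": hwe.df,
                "p_hwe": hwe.p_value,
                "hwe_stars": significance_stars(hwe.p_value),
                "Ho": div.ho,
                "He": div.he,
                "Ne": div.ne,
                "PIC": div.pic,
                "MAF": div.maf,
            }
        )
    return pd.DataFrame(rows)
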