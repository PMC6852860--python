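"""Single-locus additive and dominance effects from genotype means.

Classical Falconer-Mackay reparameterization of the three genotype means
of a biallelic locus: with homozygote means M11 (lexically first allele)
and M22 and heterozygote mean M12,

    a = (M22 - M11) / 2        additive effect
    d = M12 - (M11 + M22) / 2  dominance deviation
    degree of dominance = d / a  (undefined when |a| is negligible)

Effects are computed on least-square means rather than raw means, so they
inherit the covariate adjustment of the association stage.  The sign
convention puts the lexically first-listed homozygote as the subtrahend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .popgen import significance_stars

__all__ = [
    "GeneActionEstimate",
    "NotEstimableError",
    "additive_effect",
    "dominance_effect",
    "degree_of_dominance",
    "estimate_from_lsm",
    "gene_action_table",
]


class NotEstimableError(ValueError):
    """A genotype class needed for the effect is missing."""


@dataclass(frozen=True)
class GeneActionEstimate:
    marker: str
    trait: str
    a: float
    d: float
    degree: float | None  # None flags |a| below tolerance
    overall_p: float | None = None


def _require(value: float | None, what: str) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise NotEstimableError(f"missing {what} mean")
    return float(value)


def additive_effect(mean_hom_first: float, mean_hom_second: float) -> float:
    """a = (second homozygote - first homozygote) / 2, alleles in lexical order."""
    m1 = _require(mean_hom_first, "first-homozygote")
    m2 = _require(mean_hom_second, "second-homozygote")
    return (m2 - m1) / 2.0


def dominance_effect(
    mean_het: float, mean_hom_first: float, mean_hom_second: float
) -> float:
    """d = heterozygote - midpoint of the two homozygotes."""
    mh = _require(mean_het, "heterozygote")
    m1 = _require(mean_hom_first, "first-homozygote")
    m2 = _require(mean_hom_second, "second-homozygote")
    return mh - (m1 + m2) / 2.0


def degree_of_dominance(a: float, d: float, tolerance: float = 1e-9) -> float | None:
    """d/a, or None when |a| <= tolerance (no division by a negligible effect)."""
    if abs(a) <= tolerance:
        return None
    return d / a


def _classify(genotype: str) -> str:
    g = str(genotype)
    if len(g) != 2:
        raise ValueError(f"genotype {genotype!r} is not a two-allele call")
    if g[0] == g[1]:
        return "hom"
    return "het"


def estimate_from_lsm(
    marker: str,
    trait: str,
    lsm_by_genotype: dict[str, float],
    overall_p: float | None = None,
    tolerance: float = 1e-9,
) -> GeneActionEstimate:
    """Gene-action estimate from a {genotype: LSM} mapping for one marker.

    The two homozygotes are ordered by their (single) allele symbol; the
    heterozygote is recognized irrespective of written allele order.  A
    missing homozygote or heterozygote class raises
    :class:`NotEstimableError` (e.g. a marker where one homozygote never
    occurs in the cohort).
    """
    homs: dict[str, float] = {}
    het: float | None = None
    for g, v in lsm_by_genotype.items():
        if _classify(g) == "hom":
            homs[g[0]] = float(v)
        else:
            het = float(v)
    if len(homs) != 2:
        raise NotEstimableError(
            f"marker {marker} trait {trait!r}: need both homozygote classes, "
            f"got {sorted(homs)}"
        )
    if het is None:
        raise NotEstimableError(f"marker {marker} trait {trait!r}: no heterozygote class")
    first, second = sorted(homs)
    a = additive_effect(homs[first], homs[second])
    d = dominance_effect(het, homs[first], homs[second])
    scale = max(abs(homs[first]), abs(homs[second]), abs(het), 1.0)
    return GeneActionEstimate(
        marker=marker,
        trait=trait,
        a=a,
        d=d,
        degree=degree_of_dominance(a, d, tolerance=tolerance * scale),
        overall_p=overall_p,
    )


def gene_action_table(lsm_table: pd.DataFrame) -> pd.DataFrame:
    """Gene-action estimates for every (trait, marker) pair in an LSM table.

    ``lsm_table`` is long format with columns trait, marker, genotype, lsm
    and optionally overall_p.  Pairs whose genotype classes are incomplete
    (a missing homozygote, as for a marker with an absent genotype class)
    are reported with NaN effects and flagged not estimable rather than
    dropped.
    """
    rows = []
    has_p = "overall_p" in lsm_table.columns
    for (trait, marker), sub in lsm_table.groupby(["trait", "marker"], sort=False):
        lsm_map = dict(zip(sub["genotype"].astype(str), sub["lsm"].astype(float)))
        p = float(sub["overall_p"].iloc[0]) if has_p else None
        try:
            est = estimate_from_lsm(str(marker), str(trait), lsm_map, overall_p=p)
            rows.append(
                {
                    "trait": trait,
                    "marker": marker,
                    "additive": est.a,
                    "dominance": est.d,
                    "degree": est.degree if est.degree is not None else float("nan"),
                    "overall_p": p,
                    "stars": significance_stars(p) if p is not None else "",
                    "estimable": True,
                }
            )
        except NotEstimableError:
            rows.append(
                {
                    "trait": trait,
                    "marker": marker,
                    "additive": float("nan"),
                    "dominance": float("nan"),
                    "degree": float("nan"),
                    "overall_p": p,
                    "stars": significance_stars(p) if p is not None else "",
                    "estimable": False,
                }
            )
    return pd.DataFrame(rows)
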