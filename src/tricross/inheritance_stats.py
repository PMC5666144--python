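"""Inheritance arithmetic and exact tests for backcross panels.

Covers three questions a breeding analysis asks:

* how much donor genome *should* remain after n backcrosses without a
  linked marker (0.5^n of the genome, hence 0.5^n x G of G genes);
* is the fertile:sterile segregation compatible with a single causal
  locus (exact binomial test against 1:1); and
* which genotyped markers co-segregate with the trait (two-sided
  Fisher's exact test per marker on the donor/recurrent x
  fertile/sterile 2x2 table, Bonferroni-corrected over the marker
  family), then where the candidate locus lies (the maximal run of
  adjacent significant markers).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .genome_io import (
    DONOR,
    MISSING,
    RECURRENT,
    GenomeIOError,
    GenotypeTable,
    PhenotypeTable,
)

__all__ = [
    "RetentionExpectation",
    "AssociationResult",
    "CandidateLocus",
    "expected_retention",
    "segregation_test",
    "associate_markers",
    "rank_candidate_locus",
]


@dataclass(frozen=True)
class RetentionExpectation:
    """Expected unselected donor-genome retention after n backcrosses."""

    n_backcrosses: int
    genome_genes: int
    expected_fraction: float
    expected_genes: int
    expected_genes_continuous: float


def expected_retention(n: int, G: int) -> RetentionExpectation:
    """Leslie-style expectation: fraction 0.5^n, genes round(0.5^n * G).

    ``n`` counts total crosses (the initial cross plus backcrosses), so
    ten rounds give 0.5^10 ~ 9.77e-4, or 9 of 9,127 genes.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if G < 1:
        raise ValueError("G must be >= 1")
    frac = 0.5 ** n
    cont = frac * G
    return RetentionExpectation(
        n_backcrosses=n,
        genome_genes=G,
        expected_fraction=frac,
        expected_genes=int(round(cont)),
        expected_genes_continuous=cont,
    )


def segregation_test(n_fertile: int, n_sterile: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p-value for a 1:1 segregation hypothesis.

    Two-sidedness by minimum-likelihood summation: the p-value sums the
    probabilities of all outcomes no more likely than the observed one.
    """
    n = n_fertile + n_sterile
    if n < 1:
        raise ValueError("need at least one scored progeny")
    return float(stats.binomtest(n_fertile, n, p0, alternative="two-sided").pvalue)


@dataclass(frozen=True)
class AssociationResult:
    """One marker's 2x2 association with fertility."""

    marker: tuple[str, int]
    # counts: [donor, recurrent] x [fertile, sterile], complete cases only
    contingency: tuple[tuple[int, int], tuple[int, int]]
    n_missing: int
    p_value: float
    adjusted_p: float
    odds_direction: str  # donor_with_fertile | donor_with_sterile | none

    @property
    def significant(self) -> bool:
        return self.adjusted_p < 0.05


def associate_markers(
    genotypes: GenotypeTable,
    phenotypes: PhenotypeTable,
    correction: str = "bonferroni",
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """Fisher's exact test of donor-allele carriage against fertility.

    Markers with missing calls are tested on complete cases, with the
    number of dropped individuals reported.  ``correction`` is
    ``bonferroni`` (multiply by the number of markers tested) or
    ``none``.  Constant markers get p = 1 (no association possible).
    """
    phenotypes.require_cover(genotypes)
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    fert = np.array(
        [phenotypes.fertility[i] == "fertile" for i in genotypes.individuals]
    )
    if fert.all() or not fert.any():
        raise GenomeIOError("association undefined: a phenotype class is empty")
    m = len(genotypes.markers)
    results: list[AssociationResult] = []
    for j, marker in enumerate(genotypes.markers):
        col = genotypes.calls[:, j]
        keep = col != MISSING
        a = int(np.sum((col == DONOR) & fert & keep))       # donor, fertile
        b = int(np.sum((col == DONOR) & ~fert & keep))      # donor, sterile
        c = int(np.sum((col == RECURRENT) & fert & keep))   # recurrent, fertile
        d = int(np.sum((col == RECURRENT) & ~fert & keep))  # recurrent, sterile
        table = np.array([[a, b], [c, d]])
        if table[0].sum() == 0 or table[1].sum() == 0:
            p = 1.0
        else:
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        adj = min(1.0, p * m) if correction == "bonferroni" else p
        # direction from diagonal dominance of the observed table
        if a * d > b * c:
            direction = "donor_with_fertile"
        elif a * d < b * c:
            direction = "donor_with_sterile"
        else:
            direction = "none"
        results.append(
            AssociationResult(
                marker=marker,
                contingency=((a, b), (c, d)),
                n_missing=int(np.sum(~keep)),
                p_value=p,
                adjusted_p=adj,
                odds_direction=direction,
            )
        )
    return results


@dataclass(frozen=True)
class CandidateLocus:
    """The localized trait interval: a run of adjacent significant markers."""

    group_id: str | None
    start: int | None
    end: int | None
    markers: tuple[tuple[str, int], ...]
    contains_truth: bool | None = None
    notice: str | None = None

    @property
    def empty(self) -> bool:
        return not self.markers


def rank_candidate_locus(
    results: Sequence[AssociationResult],
    alpha: float = 0.05,
    truth_locus: tuple[str, int] | None = None,
) -> CandidateLocus:
    """Longest run of adjacent markers significant after correction.

    Markers are taken in their genotyping order; runs cannot cross
    linkage groups.  Ties between equally long runs resolve to the one
    with the smallest minimum p.  With the true causal marker supplied
    (simulations), reports whether it lies inside the interval.
    """
    sig = [r.adjusted_p < alpha for r in results]
    runs: list[tuple[int, int]] = []
    i = 0
    while i < len(results):
        if sig[i]:
            j = i
            while (
                j + 1 < len(results)
                and sig[j + 1]
                and results[j + 1].marker[0] == results[i].marker[0]
            ):
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    if not runs:
        return CandidateLocus(
            None, None, None, (), notice="no marker significant after correction"
        )
    def run_key(r):
        length = r[1] - r[0] + 1
        min_p = min(res.adjusted_p for res in results[r[0] : r[1] + 1])
        return (-length, min_p)
    best = min(runs, key=run_key)
    members = tuple(r.marker for r in results[best[0] : best[1] + 1])
    group = members[0][0]
    start = min(p for _, p in members)
    end = max(p for _, p in members)
    contains = None
    if truth_locus is not None:
        contains = truth_locus[0] == group and start <= truth_locus[1] <= end
    return CandidateLocus(group, start, end, members, contains_truth=contains)
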