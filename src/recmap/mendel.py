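"""Single-locus cross models for a fully penetrant recessive phenotype.

Two genetic hypotheses explain an F2 in which both parents are heterozygous
and one quarter of the offspring are affected:

``recessive_causal``
    A recessive mutation *a* causes the phenotype; affected fish are *aa*.
``dominant_inhibitor``
    The population is fixed for the causal mutation but a dominant
    inhibitor allele *B* suppresses the phenotype; affected fish are the
    *bb* quarter that carries no inhibitor.

Both hypotheses predict a 1:3 affected:unaffected segregation and a
theoretical allele-frequency difference of 2/3 between the phenotype-defined
offspring pools; they differ in which pool fixes the tracked allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats

from .core import GT_HET, GT_HOM_ALT, GT_HOM_REF, GT_NO_CALL, Role

HYPOTHESES = ("recessive_causal", "dominant_inhibitor")

# Expected frequency of the tracked (mutant) allele per library role.
# Under the recessive model the affected pool fixes the mutant allele and the
# unaffected pool carries it at 1/3 (AA:Aa = 1:2 among unaffected).  Under the
# inhibitor model the affected pool is the bb quarter (no inhibitor allele)
# and the unaffected 3/4 carry the B allele at 2/3.
_EXPECTED: dict[tuple[str, Role], Fraction] = {
    ("recessive_causal", Role.PARENT): Fraction(1, 2),
    ("recessive_causal", Role.AFFECTED_POOL): Fraction(1, 1),
    ("recessive_causal", Role.UNAFFECTED_POOL): Fraction(1, 3),
    ("dominant_inhibitor", Role.PARENT): Fraction(1, 2),
    ("dominant_inhibitor", Role.AFFECTED_POOL): Fraction(0, 1),
    ("dominant_inhibitor", Role.UNAFFECTED_POOL): Fraction(2, 3),
}


def _check_hypothesis(hypothesis: str) -> str:
    if hypothesis not in HYPOTHESES:
        raise ValueError(
            f"unknown hypothesis {hypothesis!r}; expected one of {HYPOTHESES}"
        )
    return hypothesis


def expected_pool_allele_freq(hypothesis: str, library_role: Role | str) -> float:
    """Expected frequency of the segregating mutant allele in a library.

    Parameters
    ----------
    hypothesis:
        ``"recessive_causal"`` or ``"dominant_inhibitor"``.
    library_role:
        ``parent``, ``affected_pool`` or ``unaffected_pool``.
    """
    _check_hypothesis(hypothesis)
    role = Role(library_role)
    if role is Role.INDIVIDUAL:
        raise ValueError("expected frequencies are defined for cross libraries, "
                         "not outside individuals")
    return float(_EXPECTED[(hypothesis, role)])


def theoretical_daf(hypothesis: str) -> float:
    """Theoretical |AF(affected pool) - AF(unaffected pool)|.

    Equals 2/3 under both hypotheses: the pools fix opposite alleles but the
    magnitude of the difference is the same.
    """
    aff = expected_pool_allele_freq(hypothesis, Role.AFFECTED_POOL)
    unaff = expected_pool_allele_freq(hypothesis, Role.UNAFFECTED_POOL)
    return abs(aff - unaff)


@dataclass(frozen=True)
class SegregationTest:
    """Result of a Pearson goodness-of-fit test against a segregation ratio."""

    observed_affected: int
    observed_unaffected: int
    ratio: tuple[float, float]
    expected_affected: float
    expected_unaffected: float
    chi2: float
    p: float


def segregation_chi2(
    n_affected: int,
    n_unaffected: int,
    ratio: tuple[float, float] = (1, 3),
) -> SegregationTest:
    """Pearson chi-square goodness of fit of observed counts to a ratio.

    One degree of freedom, no continuity correction.  ``ratio`` gives the
    expected weights (affected, unaffected); the default 1:3 is the
    recessive-locus expectation for an intercross of two heterozygotes.
    """
    if n_affected < 0 or n_unaffected < 0:
        raise ValueError("counts must be non-negative")
    total = n_affected + n_unaffected
    if total == 0:
        raise ValueError("at least one observation is required")
    w_aff, w_unaff = ratio
    if w_aff <= 0 or w_unaff <= 0:
        raise ValueError("ratio weights must be positive")
    w_sum = w_aff + w_unaff
    expected = np.array([total * w_aff / w_sum, total * w_unaff / w_sum])
    observed = np.array([n_affected, n_unaffected], dtype=float)
    chi2, p = stats.chisquare(observed, f_exp=expected)
    return SegregationTest(
        observed_affected=int(n_affected),
        observed_unaffected=int(n_unaffected),
        ratio=(float(w_aff), float(w_unaff)),
        expected_affected=float(expected[0]),
        expected_unaffected=float(expected[1]),
        chi2=float(chi2),
        p=float(p),
    )


@dataclass(frozen=True)
class ConcordanceReport:
    """Cross-tabulation of diagnostic genotype calls against phenotypes."""

    table: dict[tuple[str, str], int]
    concordant: bool
    discordant: tuple[int, ...]
    n_no_call: int
    all_no_call: bool


def diagnostic_concordance(genotype_calls, phenotypes) -> ConcordanceReport:
    """Check genotype-phenotype concordance under the recessive model.

    Perfect concordance means every affected individual is homozygous for the
    mutant allele and no unaffected individual is.  ``no_call`` genotypes are
    excluded from the verdict but counted; if every call is ``no_call`` the
    report is vacuously concordant and flagged via ``all_no_call``.

    Parameters
    ----------
    genotype_calls:
        Sequence of genotype codes (``GT_HOM_REF``/``GT_HET``/``GT_HOM_ALT``/
        ``GT_NO_CALL``) or their string labels.
    phenotypes:
        Sequence of ``"affected"`` / ``"unaffected"`` of the same length.
    """
    label_to_code = {"hom_ref": GT_HOM_REF, "het": GT_HET,
                     "hom_alt": GT_HOM_ALT, "no_call": GT_NO_CALL}
    calls = [label_to_code[g] if isinstance(g, str) else int(g)
             for g in genotype_calls]
    phen = list(phenotypes)
    if len(calls) != len(phen):
        raise ValueError(
            f"{len(calls)} genotype calls but {len(phen)} phenotypes"
        )
    for ph in phen:
        if ph not in ("affected", "unaffected"):
            raise ValueError(f"unknown phenotype {ph!r}")
    valid_codes = {GT_HOM_REF, GT_HET, GT_HOM_ALT, GT_NO_CALL}
    for g in calls:
        if g not in valid_codes:
            raise ValueError(f"unknown genotype code {g!r}")

    table: dict[tuple[str, str], int] = {}
    discordant: list[int] = []
    n_no_call = 0
    from .core import GT_LABELS

    for i, (g, ph) in enumerate(zip(calls, phen)):
        key = (GT_LABELS[g], ph)
        table[key] = table.get(key, 0) + 1
        if g == GT_NO_CALL:
            n_no_call += 1
            continue
        if ph == "affected" and g != GT_HOM_ALT:
            discordant.append(i)
        elif ph == "unaffected" and g == GT_HOM_ALT:
            discordant.append(i)

    all_no_call = n_no_call == len(calls) and len(calls) > 0
    return ConcordanceReport(
        table=table,
        concordant=len(discordant) == 0,
        discordant=tuple(discordant),
        n_no_call=n_no_call,
        all_no_call=all_no_call,
    )
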