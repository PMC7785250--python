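"""Tajima relative rate test and substitution-timing classification.

Given a gapless-column alignment of two ingroup sequences and an outgroup,
a column where ingroup 1 differs from ingroup 2 while ingroup 2 matches the
outgroup is a substitution specific to lineage 1 (and symmetrically for
lineage 2). The test statistic chi2 = (m1 - m2)^2 / (m1 + m2) is compared to
a chi-square distribution with 1 df; equal rates predict m1 ~= m2.

When a TE captured the region from lineage 1 at some point along that
branch, the TE's allele at each lineage-1-specific site dates the
substitution: a TE matching the ingroup-2 (ancestral proxy) allele predates
nothing — the substitution happened after the capture; a TE matching the
derived ingroup-1 allele means the substitution preceded the capture.
"""

from __future__ import annotations

from typing import Sequence

from scipy import stats

from .types import NUCLEOTIDES, RateTestResult, TimingCounts


def lineage_specific_substitutions(
    ingroup1: str, ingroup2: str, outgroup: str
) -> tuple[int, int, dict]:
    """Count lineage-specific substitutions from three aligned sequences.

    Returns ``(m1, m2, details)`` where details holds the contributing column
    indices (``m1_sites``, ``m2_sites``) and ``n_excluded`` — columns skipped
    for gaps, ambiguity codes, three distinct states, or outgroup-only
    differences.
    """
    if not (len(ingroup1) == len(ingroup2) == len(outgroup)):
        raise ValueError(
            f"aligned lengths differ: {len(ingroup1)}, {len(ingroup2)}, {len(outgroup)}"
        )
    m1_sites: list[int] = []
    m2_sites: list[int] = []
    n_excluded = 0
    for i, (a, b, o) in enumerate(zip(ingroup1.upper(), ingroup2.upper(), outgroup.upper())):
        if a not in NUCLEOTIDES or b not in NUCLEOTIDES or o not in NUCLEOTIDES:
            n_excluded += 1
            continue
        if a == b:
            if o != a:
                n_excluded += 1  # outgroup-only difference, unpolarizable here
            continue
        if b == o:
            m1_sites.append(i)
        elif a == o:
            m2_sites.append(i)
        else:
            n_excluded += 1  # three distinct states
    details = {
        "m1_sites": m1_sites,
        "m2_sites": m2_sites,
        "n_excluded": n_excluded,
    }
    return len(m1_sites), len(m2_sites), details


def tajima_chi2(m1: int, m2: int) -> tuple[float, float]:
    """Relative-rate chi-square statistic and upper-tail p at 1 df.

    chi2 = (m1 - m2)^2 / (m1 + m2); no continuity correction.
    """
    if m1 < 0 or m2 < 0:
        raise ValueError("substitution counts must be non-negative")
    if m1 + m2 == 0:
        raise ValueError("test undefined: m1 + m2 = 0")
    chi2 = (m1 - m2) ** 2 / (m1 + m2)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def relative_rate_test(ingroup1: str, ingroup2: str, outgroup: str) -> RateTestResult:
    """Full relative-rate test from three aligned sequences."""
    m1, m2, details = lineage_specific_substitutions(ingroup1, ingroup2, outgroup)
    chi2, p = tajima_chi2(m1, m2)
    return RateTestResult(
        m1=m1,
        m2=m2,
        chi2=chi2,
        p=p,
        m1_sites=details["m1_sites"],
        m2_sites=details["m2_sites"],
        n_excluded_columns=details["n_excluded"],
    )


def classify_substitution_timing(
    m1_sites: Sequence[int],
    ingroup1: str,
    ingroup2: str,
    te_sequence_aligned: str,
) -> TimingCounts:
    """Label each ingroup-1-specific site by the allele the TE carries.

    ``te_sequence_aligned`` shares the column space of the ingroup sequences;
    columns where the TE has a gap or ambiguity code (no TE coverage) count
    as ``n_other``, as do TE alleles matching neither ingroup.
    """
    te = te_sequence_aligned.upper()
    n_match_i2 = n_match_i1 = n_other = 0
    for i in m1_sites:
        t = te[i] if i < len(te) else "-"
        if t not in NUCLEOTIDES:
            n_other += 1
        elif t == ingroup2[i].upper():
            n_match_i2 += 1
        elif t == ingroup1[i].upper():
            n_match_i1 += 1
        else:
            n_other += 1
    return TimingCounts(
        n_te_matches_ingroup2=n_match_i2,
        n_te_matches_ingroup1=n_match_i1,
        n_other=n_other,
    )
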