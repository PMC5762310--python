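"""Independent oracles used by the test suite.

These are deliberately separate, literal codings of the decision rules and
distributions under test — direct transcriptions of the rule statements and
brute-force enumeration — and share no code with the implementation.
"""

from fractions import Fraction
from math import comb


def burden_rule_oracle(
    ac_case, an_case, ac_ctrl, an_ctrl, ac_panel, an_panel, carrier_cases,
    threshold=Fraction(3, 2), min_cases=3,
):
    """Literal transcription of the gene burden decision rule.

    A gene is enriched when the case allele frequency exceeds the threshold
    fold against BOTH control groups, or when both control groups carry zero
    alleles and the gene's deleterious alleles appear in at least
    ``min_cases`` distinct case samples.  When exactly one control group has
    zero frequency that side counts as infinitely enriched; the other side
    decides and at least one case carrier is required.

    Frequencies are exact rationals so threshold comparisons (e.g. a ratio of
    exactly 1.5) are decided without floating-point rounding.
    """
    threshold = Fraction(threshold)
    af_case = Fraction(ac_case, an_case) if an_case else Fraction(0)
    af_ctrl = Fraction(ac_ctrl, an_ctrl) if an_ctrl else Fraction(0)
    af_panel = Fraction(ac_panel, an_panel) if an_panel else Fraction(0)

    if af_ctrl == 0 and af_panel == 0:
        return carrier_cases >= min_cases
    if af_ctrl > 0 and af_panel > 0:
        return af_case > threshold * af_ctrl and af_case > threshold * af_panel
    nonzero = af_ctrl if af_ctrl > 0 else af_panel
    return af_case > threshold * nonzero and carrier_cases >= 1


def hypergeom_tail_oracle(k, n, K, N):
    """P(X >= k) for X ~ Hypergeometric(N, K, n) by exact integer enumeration."""
    denom = comb(N, n)
    total = sum(
        comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1)
    )
    return total / denom
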