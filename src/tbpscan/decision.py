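"""Allele comparison: Z-score, significance bin, direction, and rank.

Because TBP-promoter affinity correlates linearly with transcription
magnitude, a significant affinity gain of the minor allele is read as
predicted overexpression (excess) and a significant loss as underexpression
(deficiency); anything not significant at the 0.05 level is the norm.

The p-value is the two-sided standard-normal tail of the Z statistic.  The
published tables pair Z with discrete significance bins through an
unspecified mapping that is not the standard-normal tail; this module
documents and uses the standard mapping, and exposes the bin thresholds so
an alternative binning can be configured.  No multiple-testing correction is
applied across SNPs: each comparison is reported at its per-SNP level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .affinity import AffinityEstimate
from .records import ALPHA_LEVELS, Delta, Rank

#: (threshold, rank) pairs for the discrete significance bins, best first.
ALPHA_BINS: tuple[tuple[float, Rank], ...] = tuple(
    zip(ALPHA_LEVELS[:-1], (Rank.A, Rank.B, Rank.C, Rank.D)))

#: p-values above this are insignificant (norm, alpha bin 1, rank E).
SIGNIFICANCE_CUTOFF = 0.05


@dataclass(frozen=True)
class AlleleComparison:
    """Verdict of comparing the minor allele's affinity against the ancestral.

    ``z`` is positive when the minor allele binds TBP more tightly.
    """

    z: float
    p_value: float
    alpha_bin: float
    delta: Delta
    rank: Rank


def bin_alpha_rank(p_value: float,
                   bins: tuple[tuple[float, Rank], ...] = ALPHA_BINS) -> tuple[float, Rank]:
    """Map a p-value to the smallest discrete bin containing it.

    Returns ``(1, Rank.E)`` for anything above the last threshold; the bins
    are exhaustive and mutually exclusive on (0, 1].
    """
    if not 0.0 < p_value <= 1.0:
        raise ValueError(f"p-value must be in (0, 1], got {p_value}")
    for threshold, rank in bins:
        if p_value <= threshold:
            return threshold, rank
    return 1.0, Rank.E


def compare_alleles(wt: AffinityEstimate, mut: AffinityEstimate,
                    significance_cutoff: float = SIGNIFICANCE_CUTOFF) -> AlleleComparison:
    """Z-test of the two alleles' -ln K_D estimates.

    z = (mut - wt) / sqrt(wt_eps^2 + mut_eps^2); two-sided normal p-value;
    direction is excess/deficiency only when p <= ``significance_cutoff``.
    """
    if wt.epsilon <= 0 or mut.epsilon <= 0:
        raise ValueError("epsilons must be positive")
    z = (mut.minus_ln_kd - wt.minus_ln_kd) / math.hypot(wt.epsilon, mut.epsilon)
    # floored so an underflowing far-tail survives the (0, 1] domain check
    p_value = max(min(2.0 * stats.norm.sf(abs(z)), 1.0), 1e-300)
    alpha_bin, rank = bin_alpha_rank(p_value)
    if p_value > significance_cutoff:
        delta = Delta.NORM
    elif z > 0:
        delta = Delta.EXCESS
    else:
        delta = Delta.DEFICIENCY
    return AlleleComparison(z=z, p_value=p_value, alpha_bin=alpha_bin,
                            delta=delta, rank=rank)
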