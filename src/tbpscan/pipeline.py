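"""Batch annotation of promoter variants and the direction-ratio cross-check.

``annotate_variants`` runs the full per-variant chain — apply the allele
edit, estimate both alleles' affinities, compare them — and emits one marker
record per variant in input order.  ``direction_ratio_test`` checks whether
the split of significant markers into affinity-decreasing vs
affinity-increasing is consistent with the genome-wide 2:1
decrease:increase ratio of regulatory SNPs.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .affinity import ModelParameters, estimate_affinity
from .decision import compare_alleles
from .errors import TbpScanError
from .records import Delta, MarkerRecord, Rank, format_alpha
from .sequence_io import PromoterRegion, VariantSpec, apply_variant

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerRecord", "annotate_variants", "count_directions",
    "direction_ratio_test", "direction_ratio_exact", "render_report",
    "round_to_2_significant",
]


def round_to_2_significant(value: float) -> float:
    """Round to 2 significant figures, the table convention for K_D in nM."""
    if value == 0 or not math.isfinite(value):
        return value
    return round(value, 1 - int(math.floor(math.log10(abs(value)))))


def _region_for(variant: VariantSpec, regions: Sequence[PromoterRegion]) -> PromoterRegion:
    if variant.gene_symbol is not None:
        matches = [r for r in regions if r.gene_symbol == variant.gene_symbol]
    else:
        context = variant.flank5 + variant.ref_sequence + variant.flank3
        matches = [r for r in regions if context in r.sequence]
    if len(matches) != 1:
        raise TbpScanError(
            f"{variant.variant_id}: maps to {len(matches)} regions, need exactly 1")
    return matches[0]


def annotate_variants(regions: Sequence[PromoterRegion],
                      variants: Iterable[VariantSpec],
                      params: ModelParameters,
                      annotations: Mapping[str, str] | None = None,
                      on_error: str = "raise") -> list[MarkerRecord]:
    """Annotate each variant against its (unique) promoter region.

    Variants carrying a ``gene_symbol`` are matched by gene; otherwise the
    unique region containing the flank context is used.  ``on_error`` is
    ``"raise"`` (fail fast) or ``"skip"`` (log and continue).
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    records = []
    for variant in variants:
        try:
            region = _region_for(variant, regions)
            mutant = apply_variant(region, variant)
            wt_est = estimate_affinity(region.sequence, params)
            mut_est = estimate_affinity(mutant, params)
            comparison = compare_alleles(wt_est, mut_est)
        except TbpScanError:
            if on_error == "raise":
                raise
            logger.warning("skipping %s after error", variant.variant_id, exc_info=True)
            continue
        records.append(MarkerRecord(
            gene_symbol=region.gene_symbol,
            variant_id=variant.variant_id,
            flank5=variant.flank5,
            wt_allele=variant.ref_allele,
            mut_allele=variant.alt_allele,
            flank3=variant.flank3,
            kd_wt_nM=wt_est.kd_nM,
            kd_mut_nM=mut_est.kd_nM,
            delta=comparison.delta,
            z=comparison.z,
            alpha=comparison.alpha_bin,
            rank=comparison.rank,
            annotation=(annotations or {}).get(variant.variant_id, ""),
        ))
    return records


def count_directions(records: Iterable[MarkerRecord]) -> tuple[int, int]:
    """(number of deficiency markers, number of excess markers)."""
    down = up = 0
    for rec in records:
        if rec.delta is Delta.DEFICIENCY:
            down += 1
        elif rec.delta is Delta.EXCESS:
            up += 1
    return down, up


def direction_ratio_test(n_down: int, n_up: int, p0: float = 2 / 3) -> tuple[float, float]:
    """One-sided normal-approximation test of the decrease fraction vs p0.

    Returns ``(z, p)``: z = (n_down - n*p0) / sqrt(n*p0*(1-p0)); the tail is
    chosen by the sign of the observed deviation (lower tail when fewer
    decreases than expected, upper tail otherwise), matching how the 5:19
    split is compared against the genome-wide 2:1 null.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    n = n_down + n_up
    if n < 1:
        raise ValueError("need at least one direction call")
    z = (n_down - n * p0) / math.sqrt(n * p0 * (1.0 - p0))
    p = stats.norm.cdf(z) if n_down < n * p0 else stats.norm.sf(z)
    return z, float(p)


def direction_ratio_exact(n_down: int, n_up: int, p0: float = 2 / 3) -> float:
    """Exact binomial tail matching :func:`direction_ratio_test`'s direction.

    Kept alongside the normal approximation as an independent cross-check.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    n = n_down + n_up
    if n < 1:
        raise ValueError("need at least one direction call")
    if n_down < n * p0:
        return float(stats.binom.cdf(n_down, n, p0))
    return float(stats.binom.sf(n_down - 1, n, p0))


_DECISION_LABEL = {
    Delta.DEFICIENCY: "deficiency: significant",
    Delta.EXCESS: "excess: significant",
    Delta.NORM: "norm",
}


def render_report(record: MarkerRecord) -> str:
    """Human-readable single-variant report block.

    K_D values are printed to 2 significant figures; the Decision line
    carries exactly one of the three verdict labels.
    """
    def kd(value: float | None) -> str:
        if value is None:
            return "n/a"
        return f"{round_to_2_significant(value):g} nM"

    lines = [
        f"Gene: {record.gene_symbol}",
        f"SNP: {record.variant_id}",
        f"  wt : {record.flank5.lower()}[{record.wt_allele}]{record.flank3.lower()}"
        f"  K_D = {kd(record.kd_wt_nM)}",
        f"  mut: {record.flank5.lower()}[{record.mut_allele}]{record.flank3.lower()}"
        f"  K_D = {kd(record.kd_mut_nM)}",
        f"  Z = {record.z:.2f}" if record.z is not None else "  Z = n/a",
        f"  alpha = {format_alpha(record.alpha)}" if record.alpha is not None else "  alpha = n/a",
        f"  rank = {record.rank.value}" if record.rank is not None else "  rank = n/a",
        f"Decision: {_DECISION_LABEL[record.delta]}",
    ]
    return "\n".join(lines)
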