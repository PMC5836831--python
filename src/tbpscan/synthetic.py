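"""Synthetic promoter/variant cases and simulated EMSA titrations.

These generators make every pipeline stage testable without any database
retrieval: promoter cases are random 51-nt backgrounds with a planted
TATA-like window and a substitution whose model-forward effect is known by
construction, and the EMSA simulator produces noisy single-site binding
isotherms from a known K_D and refits it, emulating the titration design in
which a fixed, trace amount of TBP (0.3 nM) is titrated with increasing
oligonucleotide concentrations.

All generators are pure functions of their seed and arguments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .affinity import BASES, ModelParameters, estimate_affinity
from .decision import compare_alleles
from .errors import GenerationError
from .records import Delta
from .sequence_io import PromoterRegion, VariantSpec, apply_variant

REGION_LENGTH = 51
_EFFECT_DELTA = {
    "disrupting": Delta.DEFICIENCY,
    "enhancing": Delta.EXCESS,
    "neutral": Delta.NORM,
}


@dataclass(frozen=True)
class FixtureCase:
    """A synthetic promoter/variant pair with model-forward ground truth."""

    region: PromoterRegion
    variant: VariantSpec
    expected_delta: Delta
    true_kd_wt_nM: float
    true_kd_mut_nM: float
    seed: int


def _random_background(rng: np.random.Generator, gc_content: float) -> list[str]:
    p = np.array([(1 - gc_content) / 2, gc_content / 2,
                  gc_content / 2, (1 - gc_content) / 2])
    return list(rng.choice(list(BASES), size=REGION_LENGTH, p=p))


def _plant_box(rng: np.random.Generator, bases: list[str],
               params: ModelParameters, mismatches: int) -> None:
    """Overwrite a window with the PWM consensus, degraded at ``mismatches``
    randomly chosen positions (degrading enhanceable cases leaves headroom
    for an affinity-raising substitution)."""
    length = params.window_length
    start = int(rng.integers(5, REGION_LENGTH - length - 5))
    consensus = [BASES[int(np.argmax(row))] for row in params.pwm]
    if mismatches:
        # degrade informative positions only, so that restoring one of them
        # is always an affinity-raising candidate
        spread = np.ptp(params.pwm, axis=1)
        informative = np.flatnonzero(spread >= 0.5 * spread.max())
        picks = rng.choice(informative, size=min(mismatches, informative.size),
                           replace=False)
        for pos in picks:
            worst = BASES[int(np.argmin(params.pwm[pos]))]
            consensus[int(pos)] = worst
    bases[start:start + length] = consensus


def generate_promoter_case(rng_seed: int, effect: str = "disrupting",
                           gc_content: float = 0.5,
                           params: ModelParameters | None = None,
                           max_candidates: int = 500) -> FixtureCase:
    """Build a region + substitution whose model-forward direction is known.

    ``effect`` is ``disrupting`` (significant affinity loss), ``enhancing``
    (significant gain) or ``neutral`` (insignificant at the 0.05 level);
    the decision is evaluated with the same model used for scoring, so the
    expected outcome holds by construction.  Deterministic given the seed.

    The default generating model is the consensus template, whose sharp
    position weights emulate a strong canonical TATA box: there a single
    consensus-breaking substitution is decisive relative to the residual
    uncertainty, which is the regime the annotation pipeline is meant to
    detect.  Pass calibrated parameters to generate under a softer model.
    """
    if effect not in _EFFECT_DELTA:
        raise ValueError(f"effect must be one of {sorted(_EFFECT_DELTA)}")
    if not 0.0 < gc_content < 1.0:
        raise ValueError("gc_content must be in (0, 1)")
    if params is None:
        params = ModelParameters.consensus_template()
    rng = np.random.default_rng(rng_seed)
    bases = _random_background(rng, gc_content)
    _plant_box(rng, bases, params, mismatches=0 if effect != "enhancing" else 3)
    sequence = "".join(bases)
    region = PromoterRegion(gene_symbol=f"synthetic_{rng_seed}", sequence=sequence)
    wt_est = estimate_affinity(region.sequence, params)

    candidates = [(pos, base) for pos in range(REGION_LENGTH)
                  for base in BASES if base != sequence[pos]]
    order = rng.permutation(len(candidates))
    for pos, base in (candidates[i] for i in order[:max_candidates]):
        variant = _variant_at(region, pos, base)
        if variant is None:
            continue
        mut_est = estimate_affinity(apply_variant(region, variant), params)
        if compare_alleles(wt_est, mut_est).delta is _EFFECT_DELTA[effect]:
            return FixtureCase(
                region=region, variant=variant,
                expected_delta=_EFFECT_DELTA[effect],
                true_kd_wt_nM=wt_est.kd_nM, true_kd_mut_nM=mut_est.kd_nM,
                seed=rng_seed,
            )
    raise GenerationError(
        f"no substitution with effect {effect!r} within {max_candidates} candidates")


def _variant_at(region: PromoterRegion, pos: int, alt: str,
                flank: int = 10) -> VariantSpec | None:
    """Substitution variant at a region offset, or None if the flank context
    is not unique in the region."""
    seq = region.sequence
    flank5 = seq[max(0, pos - flank):pos]
    flank3 = seq[pos + 1:pos + 1 + flank]
    context = flank5 + seq[pos] + flank3
    if seq.count(context) != 1:
        return None
    return VariantSpec(
        variant_id=f"{region.gene_symbol}:pos{pos}{seq[pos]}>{alt}",
        flank5=flank5, ref_allele=seq[pos], alt_allele=alt, flank3=flank3,
        gene_symbol=region.gene_symbol,
    )


def _isotherm(concentration_nM: np.ndarray, kd_nM: float) -> np.ndarray:
    """Single-site binding isotherm L/(L + K_D), ligand in excess."""
    return concentration_nM / (concentration_nM + kd_nM)


def _isotherm_exact(concentration_nM: np.ndarray, kd_nM: float,
                    tbp_nM: float) -> np.ndarray:
    """Exact two-species equilibrium (quadratic form), no excess assumption."""
    total = concentration_nM + tbp_nM + kd_nM
    bound = (total - np.sqrt(total ** 2 - 4 * concentration_nM * tbp_nM)) / 2
    return bound / tbp_nM


def simulate_emsa_titration(true_kd_nM: float, ligand_concentrations_nM,
                            noise_sd: float, rng_seed: int,
                            exact_form: bool = False,
                            tbp_nM: float = 0.3) -> tuple[np.ndarray, float]:
    """Simulate a K_D titration and refit K_D from the noisy curve.

    Fraction bound follows the single-site isotherm (or, with
    ``exact_form=True``, the exact quadratic equilibrium at ``tbp_nM`` of
    protein) plus Gaussian noise truncated to [0, 1]; the refit is
    least-squares on the noisy points.  Returns (fraction_bound, refit K_D
    in nM).  Deterministic given the seed.
    """
    concentrations = np.asarray(ligand_concentrations_nM, dtype=float)
    if true_kd_nM <= 0:
        raise ValueError("true K_D must be positive")
    if concentrations.size == 0 or (concentrations <= 0).any():
        raise ValueError("ligand concentrations must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    if exact_form:
        def model(conc, kd):
            return _isotherm_exact(conc, kd, tbp_nM)
    else:
        model = _isotherm

    rng = np.random.default_rng(rng_seed)
    fraction = model(concentrations, true_kd_nM)
    if noise_sd > 0:
        fraction = np.clip(fraction + rng.normal(0.0, noise_sd, fraction.shape),
                           0.0, 1.0)
    with warnings.catch_warnings():
        # a single-point titration fits K_D but leaves its covariance undefined
        warnings.simplefilter("ignore", OptimizeWarning)
        popt, _ = curve_fit(model, concentrations, fraction,
                            p0=[float(np.median(concentrations))],
                            bounds=(1e-9, np.inf), maxfev=10000)
    return fraction, float(popt[0])
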