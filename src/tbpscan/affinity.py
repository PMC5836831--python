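"""Sliding-window estimator of TBP-promoter binding affinity.

The model follows the three-step picture of TBP-TATA recognition — sequence
readout, sliding along the duplex, and DNA bending — and scores a window of
``window_length`` nucleotides as a linear combination of three sequence
features:

    -ln K_D = k0 + k_pwm * S_pwm + k_slide * S_slide + k_bend * S_bend

where ``S_pwm`` is the sum of position-weight-matrix entries over the window,
and ``S_slide``/``S_bend`` are the means of per-dinucleotide stacking-energy
and propeller-twist properties over the window's L-1 dinucleotide steps.
K_D is the equilibrium dissociation constant of the TBP-DNA complex in mol/L,
so larger ``-ln K_D`` means tighter binding; the affinity of a whole promoter
region is the maximum over all contiguous windows (leftmost window on ties),
with a single model-level uncertainty ``epsilon`` (the calibration residual
standard deviation, in ln units).

The shipped default parameters are obtained by calibrating the model against
the packaged candidate-marker tables: a ridge-regularised regression first
fits the position weights to the tables' printed K_D values, then
:func:`calibrate` refits the four linear coefficients with the best-window
assignment iterated to convergence.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import (
    AlphabetError,
    CalibrationConvergenceError,
    CalibrationRankError,
    WindowLengthError,
)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)

#: 1e9 * exp(-x) maps -ln(K_D in mol/L) to K_D in nanomolar.
_NM_PER_MOLAR = 1e9


def kd_nanomolar(minus_ln_kd: float) -> float:
    """K_D in nM from -ln(K_D in mol/L); strictly decreasing in its argument."""
    return _NM_PER_MOLAR * math.exp(-minus_ln_kd)


def minus_ln_kd_from_nanomolar(kd_nM: float) -> float:
    """Inverse of :func:`kd_nanomolar`."""
    if kd_nM <= 0:
        raise ValueError("K_D must be positive")
    return -math.log(kd_nM / _NM_PER_MOLAR)


@dataclass
class ModelParameters:
    """Coefficients and lookup tables of the affinity estimator.

    pwm rows are window positions, columns A,C,G,T (additive weights).
    ``slide_scale`` and ``bend_scale`` map all 16 dinucleotides to real
    properties; ``residual_sd`` is the default per-estimate uncertainty
    epsilon in ln units.
    """

    pwm: np.ndarray
    k0: float
    k_pwm: float
    k_slide: float
    k_bend: float
    slide_scale: Mapping[str, float]
    bend_scale: Mapping[str, float]
    residual_sd: float
    window_length: int = 15
    _slide_vec: np.ndarray = field(init=False, repr=False)
    _bend_vec: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.pwm.shape != (self.window_length, 4):
            raise ValueError(
                f"pwm shape {self.pwm.shape} != ({self.window_length}, 4)")
        for name, scale in (("slide_scale", self.slide_scale),
                            ("bend_scale", self.bend_scale)):
            missing = set(DINUCLEOTIDES) - set(scale)
            if missing:
                raise ValueError(f"{name} misses dinucleotides {sorted(missing)}")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        self._slide_vec = np.array([self.slide_scale[d] for d in DINUCLEOTIDES])
        self._bend_vec = np.array([self.bend_scale[d] for d in DINUCLEOTIDES])

    # -- serialisation ------------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParameters":
        with open(path, encoding="utf-8") as handle:
            data = yaml.safe_load(handle)
        pwm = np.asarray(data["pwm"], dtype=float)
        if data.get("pwm_kind", "weights") == "probabilities":
            pwm = np.log(pwm / 0.25)
        return cls(
            pwm=pwm,
            k0=float(data["k0"]), k_pwm=float(data["k_pwm"]),
            k_slide=float(data["k_slide"]), k_bend=float(data["k_bend"]),
            slide_scale={k.upper(): float(v) for k, v in data["slide_scale"].items()},
            bend_scale={k.upper(): float(v) for k, v in data["bend_scale"].items()},
            residual_sd=float(data["residual_sd"]),
            window_length=int(data.get("window_length", 15)),
        )

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "window_length": self.window_length,
            "k0": float(self.k0), "k_pwm": float(self.k_pwm),
            "k_slide": float(self.k_slide), "k_bend": float(self.k_bend),
            "residual_sd": float(self.residual_sd),
            "pwm_kind": "weights",
            "pwm": [[float(x) for x in row] for row in self.pwm],
            "slide_scale": {k: float(v) for k, v in self.slide_scale.items()},
            "bend_scale": {k: float(v) for k, v in self.bend_scale.items()},
        }
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(data, handle, sort_keys=False)

    @classmethod
    def consensus_template(cls) -> "ModelParameters":
        """The packaged seed template (consensus TATA PWM, unit coefficients)."""
        from . import fixtures

        return cls.from_yaml(fixtures.data_path("default_template.yaml"))


def read_pwm(path: str | Path) -> np.ndarray:
    """Read a PWM from a plain whitespace table.

    Layout: comment lines start with '#'; each data line is ``A C G T``
    columns for one window position, either probabilities (rows summing to 1,
    converted to ln(p/0.25)) or additive weights (used as-is).
    """
    rows = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            values = [float(x) for x in line.split()]
            if len(values) != 4:
                raise ValueError(f"PWM rows need 4 columns, got {len(values)}")
            rows.append(values)
    pwm = np.asarray(rows, dtype=float)
    if np.allclose(pwm.sum(axis=1), 1.0, atol=1e-6) and (pwm >= 0).all():
        pwm = np.log(np.clip(pwm, 1e-12, None) / 0.25)
    return pwm


@dataclass(frozen=True)
class WindowScore:
    """Per-term breakdown of one window's score."""

    pwm: float
    slide: float
    bend: float
    minus_ln_kd: float


@dataclass(frozen=True)
class AffinityEstimate:
    """Affinity of one allele's region: -ln K_D +/- epsilon at the best window."""

    minus_ln_kd: float
    epsilon: float
    best_window_start: int
    kd_nM: float
    components: WindowScore

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in sequence], dtype=np.intp)
    except KeyError:
        bad = sorted(set(sequence) - set(BASES))
        raise AlphabetError(f"non-ACGT characters {bad} in sequence") from None


def score_window(window: str, params: ModelParameters) -> WindowScore:
    """Score a single window of exactly ``params.window_length`` nucleotides."""
    window = window.upper()
    if len(window) != params.window_length:
        raise WindowLengthError(
            f"window length {len(window)} != {params.window_length}")
    idx = _encode(window)
    s_pwm = float(params.pwm[np.arange(params.window_length), idx].sum())
    steps = idx[:-1] * 4 + idx[1:]
    s_slide = float(params._slide_vec[steps].mean())
    s_bend = float(params._bend_vec[steps].mean())
    total = (params.k0 + params.k_pwm * s_pwm
             + params.k_slide * s_slide + params.k_bend * s_bend)
    return WindowScore(pwm=s_pwm, slide=s_slide, bend=s_bend, minus_ln_kd=total)


def _window_scores(sequence: str, params: ModelParameters) -> list[tuple[int, WindowScore]]:
    """Scores for every scorable window; windows with non-ACGT bases skipped."""
    sequence = sequence.upper()
    length = params.window_length
    if len(sequence) < length:
        raise WindowLengthError(
            f"sequence length {len(sequence)} below window length {length}")
    out = []
    for start in range(len(sequence) - length + 1):
        window = sequence[start:start + length]
        if any(b not in BASES for b in window):
            continue
        out.append((start, score_window(window, params)))
    if not out:
        raise AlphabetError("no window free of non-ACGT characters")
    return out


def estimate_affinity(sequence: str, params: ModelParameters,
                      epsilon: float | None = None) -> AffinityEstimate:
    """Best-window affinity of a region (max over windows, leftmost tie).

    ``epsilon`` overrides the model-level residual standard deviation for
    this estimate only.
    """
    best_start, best = max(_window_scores(sequence, params),
                           key=lambda item: (item[1].minus_ln_kd, -item[0]))
    eps = params.residual_sd if epsilon is None else epsilon
    return AffinityEstimate(
        minus_ln_kd=best.minus_ln_kd,
        epsilon=eps,
        best_window_start=best_start,
        kd_nM=kd_nanomolar(best.minus_ln_kd),
        components=best,
    )


# ---------------------------------------------------------------------------
# Calibration against observed K_D values
# ---------------------------------------------------------------------------

#: (sequence, K_D in nM) pair used as a calibration observation.
Observation = tuple[str, float]

_N_COEFFS = 5  # k0, k_pwm, k_slide, k_bend, residual_sd


def _best_window_features(sequence: str, params: ModelParameters) -> tuple[int, np.ndarray]:
    start, score = max(_window_scores(sequence, params),
                       key=lambda item: (item[1].minus_ln_kd, -item[0]))
    return start, np.array([1.0, score.pwm, score.slide, score.bend])


def calibrate(template: ModelParameters, observations: Sequence[Observation],
              max_iter: int = 50) -> ModelParameters:
    """Least-squares fit of k0, k_pwm, k_slide, k_bend to observed K_D values.

    Each observation contributes its best window under the current
    parameters; window assignment and coefficients are iterated until the
    assignment is stable.  ``residual_sd`` becomes the root-mean-square
    residual of the final fit (floored at 1e-6 so it stays positive on
    interpolating fits).  Deterministic given inputs.
    """
    observations = list(observations)
    if len(observations) <= _N_COEFFS:
        raise CalibrationRankError(
            f"{len(observations)} observations cannot determine "
            f"{_N_COEFFS} free coefficients")
    y = np.array([minus_ln_kd_from_nanomolar(kd) for _, kd in observations])
    params = template
    assignment: tuple[int, ...] | None = None
    seen: dict[tuple[int, ...], tuple[float, ModelParameters]] = {}
    for _ in range(max_iter):
        rows = [_best_window_features(seq, params) for seq, _ in observations]
        new_assignment = tuple(start for start, _ in rows)
        X = np.vstack([features for _, features in rows])
        coeffs, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            raise CalibrationRankError(
                f"design matrix rank {rank} < {X.shape[1]}; "
                "observations do not span the model terms")
        resid = y - X @ coeffs
        rms = float(np.sqrt(np.mean(resid ** 2)))
        params = replace(
            template,
            k0=float(coeffs[0]), k_pwm=float(coeffs[1]),
            k_slide=float(coeffs[2]), k_bend=float(coeffs[3]),
            residual_sd=max(rms, 1e-6),
        )
        if new_assignment == assignment:
            return params
        if new_assignment in seen or (seen and rms >= min(v[0] for v in seen.values()) - 1e-9):
            # limit cycle, or the residual stopped improving: the assignment
            # has effectively converged; keep the best-fitting iterate
            seen.setdefault(new_assignment, (rms, params))
            return min(seen.values(), key=lambda item: item[0])[1]
        seen[new_assignment] = (rms, params)
        assignment = new_assignment
    raise CalibrationConvergenceError(
        f"best-window assignment still changing after {max_iter} iterations")


def fit_position_weights(observations: Sequence[Observation],
                         template: ModelParameters,
                         ridge: float = 1.0,
                         max_iter: int = 50) -> ModelParameters:
    """Fit the PWM itself to observed K_D values by ridge regression.

    Used to construct the default parameters when no externally determined
    position weights are available: each observation's best window is one-hot
    encoded (window_length x 4 indicators) and joined with the dinucleotide
    slide/bend means; the weights are fitted to -ln K_D with an L2 penalty
    of ``ridge`` on the one-hot block only (intercept and property terms are
    unpenalised).  Per position the four base weights are centred, the
    offset being absorbed into k0.  Window assignment is iterated to
    convergence as in :func:`calibrate`.
    """
    observations = list(observations)
    L = template.window_length
    n_onehot = 4 * L
    if len(observations) <= _N_COEFFS:
        raise CalibrationRankError("too few observations to fit position weights")
    y = np.array([minus_ln_kd_from_nanomolar(kd) for _, kd in observations])
    params = template
    assignment: tuple[int, ...] | None = None
    seen: dict[tuple[int, ...], tuple[float, ModelParameters]] = {}
    for _ in range(max_iter):
        starts, X = [], []
        for seq, _ in observations:
            start, _feat = _best_window_features(seq, params)
            window = seq.upper()[start:start + L]
            idx = _encode(window)
            onehot = np.zeros(n_onehot)
            onehot[np.arange(L) * 4 + idx] = 1.0
            steps = idx[:-1] * 4 + idx[1:]
            X.append(np.concatenate((
                [1.0], onehot,
                [params._slide_vec[steps].mean(), params._bend_vec[steps].mean()],
            )))
            starts.append(start)
        new_assignment = tuple(starts)
        X = np.vstack(X)
        penalty = np.zeros(X.shape[1])
        penalty[1:1 + n_onehot] = ridge
        beta = np.linalg.solve(X.T @ X + np.diag(penalty), X.T @ y)
        pwm = beta[1:1 + n_onehot].reshape(L, 4)
        offsets = pwm.mean(axis=1)
        pwm = pwm - offsets[:, None]
        resid = y - X @ beta
        rms = float(np.sqrt(np.mean(resid ** 2)))
        params = replace(
            template,
            pwm=pwm,
            k0=float(beta[0] + offsets.sum()),
            k_pwm=1.0,
            k_slide=float(beta[-2]),
            k_bend=float(beta[-1]),
            residual_sd=max(rms, 1e-6),
        )
        if new_assignment == assignment:
            return params
        if new_assignment in seen or (seen and rms >= min(v[0] for v in seen.values()) - 1e-9):
            # limit cycle, or the residual stopped improving: the assignment
            # has effectively converged; keep the best-fitting iterate
            seen.setdefault(new_assignment, (rms, params))
            return min(seen.values(), key=lambda item: item[0])[1]
        seen[new_assignment] = (rms, params)
        assignment = new_assignment
    raise CalibrationConvergenceError(
        f"best-window assignment still changing after {max_iter} iterations")


def observations_from_markers(records: Iterable, inserts=None) -> list[Observation]:
    """Calibration observations (allele context, printed K_D) from marker rows.

    Both alleles of every row with a printed K_D contribute; rows flagged
    ``incomplete`` are skipped.
    """
    obs: list[Observation] = []
    for rec in records:
        if "incomplete" in rec.flags:
            continue
        if rec.kd_wt_nM is not None:
            obs.append((rec.wt_sequence(inserts), rec.kd_wt_nM))
        if rec.kd_mut_nM is not None:
            obs.append((rec.mut_sequence(inserts), rec.kd_mut_nM))
    return obs


def calibrate_from_markers(records: Iterable, template: ModelParameters | None = None,
                           inserts=None, ridge: float = 1.0) -> ModelParameters:
    """Two-stage calibration on marker rows: position weights, then coefficients."""
    if template is None:
        template = ModelParameters.consensus_template()
    obs = observations_from_markers(records, inserts)
    fitted = fit_position_weights(obs, template, ridge=ridge)
    return calibrate(fitted, obs)


@functools.lru_cache(maxsize=1)
def default_parameters() -> ModelParameters:
    """Model parameters calibrated on the packaged marker tables.

    Computed on first use and cached for the process lifetime.
    """
    from . import fixtures

    return calibrate_from_markers(fixtures.load_all_tables(),
                                  inserts=fixtures.named_inserts())
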