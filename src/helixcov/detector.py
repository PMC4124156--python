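"""Helix-helix interaction detection from coupling matrices.

An interacting helix pair leaves a diagonal (parallel packing) or
anti-diagonal (antiparallel packing) stripe of elevated couplings in the
inter-helix block of the coupling matrix, recurring with the ~3.5-residue
helical periodicity.  Detection proceeds in four stages:

1. a square weighted pattern encoding the expected stripe geometry is slid
   over the inter-helix submatrix;
2. at each pattern position Bayes' theorem converts the weighted
   log-likelihood ratios of the cell strengths (interacting vs
   non-interacting gamma densities) into a raw interaction probability;
3. evidence is aggregated over pattern positions and both orientations
   (maximum by default, log-sum-exp softmax optionally);
4. raw scores are mapped to posteriors through a monotone four-parameter
   calibration curve fitted on labelled data under a Bernoulli likelihood;
   curves calibrated on several datasets are averaged weighted by dataset
   size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import ndimage, optimize, special, stats

from .annotations import HelixAnnotation, Segment
from .couplings import CouplingMatrix

_EPS_STRENGTH = 1e-8
_LLR_CLIP = 30.0


# ---------------------------------------------------------------------------
# pattern template
# ---------------------------------------------------------------------------

@dataclass
class PatternTemplate:
    """Square weight grids for parallel and antiparallel helix packing.

    ``weights_parallel[i, j]`` weights the coupling between residue ``i`` of
    the first helix and residue ``j`` of the second (both N->C); the
    antiparallel grid is the parallel grid with row order reversed.
    """

    size: int
    periodicity: float
    weights_parallel: np.ndarray
    weights_antiparallel: np.ndarray

    def __post_init__(self) -> None:
        if self.size < 3 or self.size % 2 == 0:
            raise ValueError("pattern size must be odd and >= 3")
        for w in (self.weights_parallel, self.weights_antiparallel):
            if w.shape != (self.size, self.size) or not np.all(np.isfinite(w)):
                raise ValueError("weight grids must be finite size x size")
        if not np.allclose(self.weights_antiparallel, self.weights_parallel[::-1]):
            raise ValueError("antiparallel grid must be the row-reversed parallel grid")

    @property
    def n_cells(self) -> int:
        return self.size * self.size

    def weights(self, orientation: str) -> np.ndarray:
        if orientation == "parallel":
            return self.weights_parallel
        if orientation == "antiparallel":
            return self.weights_antiparallel
        raise ValueError(f"unknown orientation: {orientation!r}")


def build_pattern_template(
    size: int = 17,
    periodicity: float = 3.5,
    amplitude: float = 1.0,
    width: float = 1.0,
    center_decay: float = 0.0,
) -> PatternTemplate:
    """Build the stripe-ridge pattern template.

    The parallel grid carries cosine ridges along diagonals of constant
    offset ``i - j``, recurring every ``periodicity`` cells and clipped at
    zero between ridges; the grid is scaled so the absolute weights sum
    to 1.  ``width`` stretches the ridge period, ``center_decay`` applies a
    Gaussian envelope away from the pattern centre, and ``amplitude``
    scales the ridge before normalisation (relevant only when combined
    with externally supplied weight components).
    """
    if size % 2 == 0:
        raise ValueError("pattern size must be odd")
    if size < 3:
        raise ValueError("pattern size must be >= 3")
    if periodicity <= 2:
        raise ValueError("periodicity must exceed 2 residues per turn")
    half = size // 2
    idx = np.arange(-half, half + 1)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    offset = ii - jj
    period = periodicity * width
    # distance from the offset diagonal to the nearest ridge
    dist = np.abs(offset - period * np.round(offset / period))
    ridge = np.clip(np.cos(2 * np.pi * dist / period), 0.0, None)
    envelope = np.exp(-center_decay * (ii**2 + jj**2) / max(half, 1) ** 2)
    w = ridge * envelope
    total = np.abs(w).sum()
    if total == 0:
        raise ValueError("degenerate template: all weights zero")
    # normalised so sum |w| = amplitude (1 by default): amplitude scales the
    # total evidence a window can contribute
    w = amplitude * w / total
    return PatternTemplate(size, periodicity, w, w[::-1].copy())


# ---------------------------------------------------------------------------
# strength distributions
# ---------------------------------------------------------------------------

@dataclass
class StrengthDistributions:
    """Gamma densities of coupling strengths at interacting (fg) and
    non-interacting (bg) residue pairs, plus the interaction prior."""

    fg_shape: float
    fg_scale: float
    bg_shape: float
    bg_scale: float
    prior: float

    def __post_init__(self) -> None:
        if not (0.0 < self.prior < 1.0):
            raise ValueError("prior must be in (0, 1)")
        for v in (self.fg_shape, self.fg_scale, self.bg_shape, self.bg_scale):
            if not (np.isfinite(v) and v > 0):
                raise ValueError("gamma parameters must be positive and finite")

    @property
    def strength_floor(self) -> float:
        """Evaluation floor for strengths: half the background mean.

        Vanishing strengths (APC clamping, zero-padded window overhang)
        are evaluated at this floor so they contribute finite,
        background-typical evidence rather than an unbounded one, and the
        heavy left tail of the log-gamma ratio is suppressed.
        """
        return 0.5 * self.bg_shape * self.bg_scale

    @property
    def fg(self) -> stats.rv_continuous:
        return stats.gamma(self.fg_shape, scale=self.fg_scale)

    @property
    def bg(self) -> stats.rv_continuous:
        return stats.gamma(self.bg_shape, scale=self.bg_scale)

    def llr(self, strengths: np.ndarray) -> np.ndarray:
        """Clipped log-likelihood ratio log fg(s) - log bg(s).

        Strengths are floored at ``strength_floor`` so that exact zeros
        (APC clamping, zero-padded window overhang) contribute finite,
        background-typical evidence.
        """
        s = np.maximum(np.asarray(strengths, dtype=float), self.strength_floor)
        out = self.fg.logpdf(s) - self.bg.logpdf(s)
        return np.clip(out, -_LLR_CLIP, _LLR_CLIP)


def fit_strength_distributions(
    labelled_pairs: Iterable[tuple[float, bool]],
    prior: float,
) -> StrengthDistributions:
    """Fit fg/bg gamma densities by maximum likelihood on labelled strengths."""
    pairs = list(labelled_pairs)
    fg = np.array([s for s, y in pairs if y], dtype=float)
    bg = np.array([s for s, y in pairs if not y], dtype=float)
    if fg.size == 0 or bg.size == 0:
        raise ValueError("both interacting and non-interacting strengths required")
    params = {}
    for name, data in (("fg", fg), ("bg", bg)):
        if np.std(data) == 0:
            raise ValueError(
                f"{name} strengths have zero variance; cannot fit a gamma density"
            )
        shape, _, scale = stats.gamma.fit(np.maximum(data, _EPS_STRENGTH), floc=0)
        params[name] = (shape, scale)
    return StrengthDistributions(
        fg_shape=params["fg"][0],
        fg_scale=params["fg"][1],
        bg_shape=params["bg"][0],
        bg_scale=params["bg"][1],
        prior=prior,
    )


# ---------------------------------------------------------------------------
# window scoring and pair scanning
# ---------------------------------------------------------------------------

def raw_window_probability(
    window: np.ndarray,
    template: PatternTemplate,
    dists: StrengthDistributions,
    orientation: str,
) -> float:
    """Bayes posterior of interaction given one pattern-sized window.

    ``logit(p) = logit(prior) + sum_cells w_cell * llr(s_cell)``.
    """
    window = np.asarray(window, dtype=float)
    if window.shape != (template.size, template.size):
        raise ValueError(
            f"window shape {window.shape} != template size {template.size}"
        )
    if not np.all(np.isfinite(window)):
        raise ValueError("window contains non-finite strengths")
    w = template.weights(orientation)
    logit = special.logit(dists.prior) + float(np.sum(w * dists.llr(window)))
    return float(special.expit(logit))


@dataclass
class HelixPairPrediction:
    """Scored (and optionally calibrated) helix pair."""

    helix_a: str
    helix_b: str
    orientation: str
    best_offset: tuple[int, int]  # reference residue numbers at the pattern centre
    raw_score: float
    posterior: float | None = None

    def __post_init__(self) -> None:
        if self.helix_a == self.helix_b:
            raise ValueError("helix pair must consist of two distinct helices")
        if not (0.0 <= self.raw_score <= 1.0):
            raise ValueError("raw_score must be a probability")
        if self.posterior is not None and not (0.0 <= self.posterior <= 1.0):
            raise ValueError("posterior must be a probability")


def _pair_submatrix(cm: CouplingMatrix, seg_a: Segment, seg_b: Segment):
    rows = np.array([cm.index_of(r) for r in seg_a.residues])
    cols = np.array([cm.index_of(r) for r in seg_b.residues])
    return cm.submatrix(rows, cols)


def scan_helix_pair(
    cm: CouplingMatrix,
    ha: HelixAnnotation,
    pair: tuple[str, str],
    template: PatternTemplate,
    dists: StrengthDistributions,
    aggregation: str = "max",
) -> HelixPairPrediction:
    """Slide the pattern over the inter-helix submatrix and aggregate.

    Every submatrix cell serves as a pattern centre; window positions
    overhanging the submatrix are zero-padded (strength 0).  The raw score
    is the maximum raw probability over positions and orientations
    (``aggregation="logsumexp"`` replaces the maximum over positions by a
    soft maximum).
    """
    name_a, name_b = pair
    if name_a == name_b:
        raise ValueError("helix pair must name two distinct helices")
    for name in pair:
        if name not in ha:
            raise KeyError(f"helix {name!r} not in annotation")
    seg_a, seg_b = ha[name_a], ha[name_b]
    if len(seg_a) < 3 or len(seg_b) < 3:
        raise ValueError("each helix needs at least 3 residues")
    sub = _pair_submatrix(cm, seg_a, seg_b)
    llr = dists.llr(sub)
    llr_zero = float(dists.llr(np.array([0.0]))[0])
    prior_logit = special.logit(dists.prior)

    best = (-np.inf, None, None)  # logit, orientation, (i, j)
    all_logits = []
    for orientation in ("parallel", "antiparallel"):
        w = template.weights(orientation)
        # correlate == sliding weighted sum with the pattern centred on each
        # cell; constant padding with llr(0) realises strength zero-padding
        field_ = ndimage.correlate(llr, w, mode="constant", cval=llr_zero)
        logits = prior_logit + field_
        all_logits.append(logits)
        idx = np.unravel_index(np.argmax(logits), logits.shape)
        if logits[idx] > best[0]:
            best = (float(logits[idx]), orientation, idx)

    if aggregation == "max":
        raw = float(special.expit(best[0]))
    elif aggregation == "logsumexp":
        stacked = np.concatenate([lg.ravel() for lg in all_logits])
        raw = float(special.expit(special.logsumexp(stacked) - np.log(stacked.size)))
    else:
        raise ValueError(f"unknown aggregation: {aggregation!r}")

    i, j = best[2]
    return HelixPairPrediction(
        helix_a=name_a,
        helix_b=name_b,
        orientation=best[1],
        best_offset=(seg_a.start + int(i), seg_b.start + int(j)),
        raw_score=raw,
    )


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _clip_prob(p: np.ndarray) -> np.ndarray:
    return np.clip(p, 1e-9, 1.0 - 1e-9)


@dataclass
class CalibrationModel:
    """Monotone 4-parameter calibration curve.

    ``cal(r) = a + (b - a) * sigmoid(c * (logit(r) - d))`` with
    ``0 <= a <= b <= 1`` and ``c > 0`` (hence non-decreasing in ``r``),
    fitted by Bernoulli maximum likelihood on unbinned labels.
    """

    a: float
    b: float
    c: float
    d: float
    bin_size: int = 60
    source_weight: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.a <= self.b <= 1.0):
            raise ValueError("need 0 <= a <= b <= 1")
        if self.c <= 0:
            raise ValueError("c must be positive (monotone curve)")

    def __call__(self, raw: np.ndarray | float) -> np.ndarray | float:
        r = _clip_prob(np.asarray(raw, dtype=float))
        out = self.a + (self.b - self.a) * special.expit(
            self.c * (special.logit(r) - self.d)
        )
        return float(out) if np.isscalar(raw) else out

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


def _curve_nll(theta: np.ndarray, lr: np.ndarray, y: np.ndarray) -> float:
    alpha, beta, gamma, d = theta
    a = special.expit(alpha)
    b = a + (1.0 - a) * special.expit(beta)
    c = np.exp(gamma)
    p = _clip_prob(a + (b - a) * special.expit(c * (lr - d)))
    return float(-np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_calibration(
    raw_and_truth: Sequence[tuple[float, bool]],
    bin_size: int = 60,
    source_weight: float | None = None,
) -> CalibrationModel:
    """Fit the 4-parameter calibration curve on labelled raw scores."""
    data = list(raw_and_truth)
    if len(data) < 2 * bin_size:
        raise ValueError(f"need at least {2 * bin_size} labelled predictions")
    raw = _clip_prob(np.array([r for r, _ in data], dtype=float))
    y = np.array([bool(t) for _, t in data], dtype=float)
    if y.min() == y.max():
        raise ValueError("labels are all one class; calibration is undefined")
    lr = special.logit(raw)

    best = None
    for gamma0 in (0.0, np.log(3.0)):
        for d0 in (0.0, float(np.median(lr))):
            x0 = np.array([special.logit(0.05), special.logit(0.9), gamma0, d0])
            res = optimize.minimize(
                _curve_nll, x0, args=(lr, y), method="Nelder-Mead",
                options={"maxiter": 4000, "xatol": 1e-7, "fatol": 1e-10},
            )
            if best is None or res.fun < best.fun:
                best = res
    alpha, beta, gamma, d = best.x
    a = float(special.expit(alpha))
    b = a + (1.0 - a) * float(special.expit(beta))
    return CalibrationModel(
        a=a, b=b, c=float(np.exp(gamma)), d=float(d),
        bin_size=bin_size,
        source_weight=float(source_weight) if source_weight is not None else float(len(data)),
    )


def calibration_curve_points(
    raw_and_truth: Sequence[tuple[float, bool]], bin_size: int = 60
) -> tuple[np.ndarray, np.ndarray]:
    """Binned empirical calibration points (diagnostic only).

    Predictions are ordered by raw score and grouped into bins of
    ``bin_size``; returns per-bin mean raw score and empirical positive
    fraction.
    """
    data = sorted(raw_and_truth, key=lambda t: t[0])
    raw = np.array([r for r, _ in data])
    y = np.array([bool(t) for _, t in data], dtype=float)
    n_bins = len(data) // bin_size
    if n_bins == 0:
        raise ValueError("fewer predictions than one bin")
    xs, ys = [], []
    for k in range(n_bins):
        sl = slice(k * bin_size, (k + 1) * bin_size)
        xs.append(raw[sl].mean())
        ys.append(y[sl].mean())
    return np.array(xs), np.array(ys)


class CombinedCalibration:
    """Size-weighted average of several calibration curves."""

    def __init__(self, models: Sequence[CalibrationModel]):
        models = list(models)
        if not models:
            raise ValueError("need at least one calibration model")
        weights = np.array([m.source_weight for m in models], dtype=float)
        if np.any(weights <= 0):
            raise ValueError("source weights must be positive")
        self.models = models
        self.weights = weights / weights.sum()

    def __call__(self, raw: np.ndarray | float) -> np.ndarray | float:
        vals = [w * np.asarray(m(raw)) for w, m in zip(self.weights, self.models)]
        out = np.sum(vals, axis=0)
        return float(out) if np.isscalar(raw) else out


def combine_calibrations(models: Sequence[CalibrationModel]) -> CombinedCalibration:
    """Average calibrated probabilities weighted by dataset size."""
    return CombinedCalibration(models)


# ---------------------------------------------------------------------------
# all-pairs prediction
# ---------------------------------------------------------------------------

def predict_all_pairs(
    cm: CouplingMatrix,
    ha: HelixAnnotation,
    template: PatternTemplate,
    dists: StrengthDistributions,
    calibration: Callable[[float], float] | None = None,
    aggregation: str = "max",
) -> list[HelixPairPrediction]:
    """One prediction per unordered helix pair, sorted by posterior.

    Ties are broken by the (helix_a, helix_b) name pair.  Without a
    calibration function the raw score is used as the posterior.
    """
    helices = ha.helices
    if len(helices) < 2:
        raise ValueError("need at least 2 helices")
    preds = []
    for x in range(len(helices)):
        for ypos in range(x + 1, len(helices)):
            p = scan_helix_pair(
                cm, ha, (helices[x].name, helices[ypos].name),
                template, dists, aggregation=aggregation,
            )
            p.posterior = (
                float(calibration(p.raw_score)) if calibration is not None
                else p.raw_score
            )
            preds.append(p)
    preds.sort(key=lambda p: (-p.posterior, p.helix_a, p.helix_b))
    return preds


# ---------------------------------------------------------------------------
# template weight optimization (low-dimensional ridge parameterization)
# ---------------------------------------------------------------------------

def optimize_pattern_weights(
    labelled_windows: Sequence[tuple[np.ndarray, bool]],
    dists: StrengthDistributions,
    size: int = 17,
    periodicity: float = 3.5,
    n_rounds: int = 2,
) -> PatternTemplate:
    """Coordinate ascent over the ridge parameters (amplitude, width, decay).

    289 free per-cell weights are unidentifiable on small training sets, so
    the search is restricted to the low-dimensional ridge family; the
    objective is the Bernoulli log-likelihood of the labels under the raw
    window probabilities (parallel orientation, windows pre-registered).
    """
    grids = {
        "amplitude": np.array([0.5, 1.0, 2.0]),
        "width": np.array([0.8, 0.9, 1.0, 1.1, 1.2]),
        "center_decay": np.array([0.0, 0.5, 1.0, 2.0]),
    }
    params = {"amplitude": 1.0, "width": 1.0, "center_decay": 0.0}

    def objective(p: dict) -> float:
        tpl = build_pattern_template(size, periodicity, **p)
        ll = 0.0
        for window, label in labelled_windows:
            prob = _clip_prob(np.array(
                raw_window_probability(window, tpl, dists, "parallel")
            ))
            ll += float(np.log(prob) if label else np.log(1 - prob))
        return ll

    for _ in range(n_rounds):
        for key, grid in grids.items():
            scores = []
            for v in grid:
                trial = dict(params)
                trial[key] = float(v)
                scores.append(objective(trial))
            params[key] = float(grid[int(np.argmax(scores))])
    return build_pattern_template(size, periodicity, **params)
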