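"""Machine-learning quality control for both pipeline stages.

Two small models, both fitted on cross-validation predictions:

* a univariate logistic regression on (log-transformed) predicted blob volume
  that detects scans not containing the L3/L4 level — the negative class is
  built by cropping each training volume so the disk is excluded;
* a univariate linear regression mapping the mean softmax entropy of the
  muscle-class probability map to the expected muscle Dice score.

A restrictive cohort policy flags the 10% of cases with the lowest predicted
muscle Dice; an absolute predicted-Dice threshold is available for streaming
(single-case) use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging import BACKGROUND, SAT, SM, VAT, CTVolume, DiskAnnotation, ProbabilityMap

__all__ = [
    "PresenceModel",
    "DiceModel",
    "QCPolicy",
    "QCDecision",
    "crop_excluding_disk",
    "fit_presence",
    "mean_entropy",
    "fit_dice_model",
    "predict_dice",
    "restrictive_exclusion",
    "qc_decide",
]

_LOG_EPS = 0.01  # ml, added before the log transform of blob volume


@dataclass
class PresenceModel:
    """Univariate logistic model: P(L3/L4 present) from predicted blob volume.

    The feature is ``log(volume_ml + eps)``; the weight is constrained to be
    non-negative so a larger blob never lowers the presence probability (a
    negative MLE slope is projected to the intercept-only majority model).
    """

    weight: float
    intercept: float
    eps: float = _LOG_EPS
    threshold: float = 0.5
    transform: str = "log_volume_ml"

    def predict_proba(self, volume_ml) -> np.ndarray:
        x = np.log(np.asarray(volume_ml, dtype=float) + self.eps)
        return 1.0 / (1.0 + np.exp(-(self.weight * x + self.intercept)))

    def predict(self, volume_ml) -> np.ndarray:
        return self.predict_proba(volume_ml) >= self.threshold


@dataclass
class DiceModel:
    """Univariate linear model: mean entropy -> predicted muscle Dice."""

    intercept: float
    slope: float
    resid_sd: float
    ci_intercept: tuple[float, float]
    ci_slope: tuple[float, float]
    n: int


@dataclass
class QCPolicy:
    """Decision policy for the two QC stages.

    ``mode='cohort_decile'`` excludes the lowest ``fraction`` of predicted
    muscle Dice within a cohort; ``mode='absolute'`` compares each case to
    ``dice_threshold`` (for streaming single-case use).
    """

    presence_threshold: float = 0.5
    mode: str = "cohort_decile"
    fraction: float = 0.10
    dice_threshold: float = 0.924


@dataclass
class QCDecision:
    presence_prob: float | None
    presence_flag: bool
    predicted_dice_sm: float | None
    excluded: bool
    reason: str  # {'absent_level', 'low_predicted_dice', 'none'}

    def __post_init__(self):
        if self.excluded and self.reason == "none":
            raise ValueError("an excluded case must carry a reason")

    def to_dict(self):
        return {"presence_prob": self.presence_prob,
                "presence_flag": self.presence_flag,
                "predicted_dice_sm": self.predicted_dice_sm,
                "excluded": self.excluded, "reason": self.reason}


# ---------------------------------------------------------------------------
# negative-set construction
# ---------------------------------------------------------------------------

def crop_excluding_disk(volume: CTVolume, annotation: DiskAnnotation,
                        margin_mm: float = 10.0, rng_seed: int = 0) -> CTVolume:
    """A contiguous z-crop of ``volume`` that does not contain the disk.

    The crop boundary stays at least ``margin_mm`` from the annotated center;
    the side (below/above) is chosen by seeded randomness among the feasible
    ones. Used to build the balanced absent-level class for presence QC.
    """
    dz = volume.spacing[0]
    disk_mm = volume.z_mm(annotation.center[0])
    z_mm = volume.origin[0] + np.arange(volume.n_slices) * dz
    below = np.flatnonzero(z_mm <= disk_mm - margin_mm)
    above = np.flatnonzero(z_mm >= disk_mm + margin_mm)
    options = []
    if len(below) >= 2:
        options.append(("below", 0, below[-1] + 1))
    if len(above) >= 2:
        options.append(("above", above[0], volume.n_slices))
    if not options:
        raise ValueError("volume too short to exclude the disk with this margin")
    rng = np.random.default_rng(rng_seed)
    side, lo, hi = options[int(rng.integers(len(options)))]
    return CTVolume(
        voxels=volume.voxels[lo:hi].copy(),
        spacing=volume.spacing,
        origin=(volume.z_mm(lo), volume.origin[1], volume.origin[2]),
        patient_id=f"{volume.patient_id}_crop_{side}",
    )


# ---------------------------------------------------------------------------
# presence model
# ---------------------------------------------------------------------------

def fit_presence(volumes_ml, labels, C: float = 10.0) -> PresenceModel:
    """Fit the logistic presence model on blob volumes from CV predictions.

    ``labels`` are 1 for volumes containing the L3/L4 level. The fit is
    maximum likelihood with weak L2 regularization (guarantees convergence on
    perfectly separated data).
    """
    from sklearn.linear_model import LogisticRegression

    v = np.asarray(volumes_ml, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes (present / absent) must be represented")
    x = np.log(v + _LOG_EPS)[:, None]
    clf = LogisticRegression(C=C, solver="lbfgs")
    clf.fit(x, y)
    w = float(clf.coef_[0, 0])
    b = float(clf.intercept_[0])
    if w < 0:  # monotonicity projection: intercept-only majority model
        p = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
        w, b = 0.0, float(np.log(p / (1 - p)))
    return PresenceModel(weight=w, intercept=b)


# ---------------------------------------------------------------------------
# entropy and the Dice regressor
# ---------------------------------------------------------------------------

def mean_entropy(prob: ProbabilityMap | np.ndarray,
                 mode: str = "binary_class_all_pixels",
                 class_code: int = SM) -> float:
    """Mean per-pixel softmax entropy of a probability map (natural log).

    ``binary_class_all_pixels`` (default): mean over all pixels of the binary
    entropy ``-[p ln p + (1-p) ln(1-p)]`` of the given class' probability —
    the muscle-class uncertainty feature. ``categorical_all_pixels``: mean
    over pixels of ``-sum_c p_c ln p_c``. ``0 ln 0 := 0``.
    """
    probs = prob.probs if isinstance(prob, ProbabilityMap) else np.asarray(prob)
    def _xlogx(p):
        return p * np.log(np.where(p > 0, p, 1.0))  # 0 ln 0 := 0

    if mode == "categorical_all_pixels":
        p = probs.astype(np.float64)
        return float(-_xlogx(p).sum(axis=0).mean())
    if mode == "binary_class_all_pixels":
        if not (0 <= class_code < probs.shape[0]):
            raise ValueError(f"unknown class code {class_code}")
        p = probs[class_code].astype(np.float64)
        return float(-(_xlogx(p) + _xlogx(1.0 - p)).mean())
    raise ValueError(f"unknown entropy mode {mode!r}")


def fit_dice_model(pairs) -> DiceModel:
    """Ordinary least squares of observed muscle Dice on mean entropy.

    ``pairs`` is an iterable of ``(mean_entropy, observed_dice)`` from the
    cross-validation predictions; needs >= 3 pairs and non-constant entropy.
    Stores the residual SD and the 95% confidence intervals of both
    coefficients.
    """
    import statsmodels.api as sm

    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (entropy, dice) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) < 1e-12:
        raise ValueError("entropy feature is constant; cannot fit a slope")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    return DiceModel(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        resid_sd=float(np.sqrt(res.scale)),
        ci_intercept=(float(ci[0, 0]), float(ci[0, 1])),
        ci_slope=(float(ci[1, 0]), float(ci[1, 1])),
        n=len(y),
    )


def predict_dice(model: DiceModel, entropy: float) -> float:
    """Predicted muscle Dice, clipped to [0, 1]."""
    if model is None:
        raise ValueError("Dice model is not fitted")
    return float(np.clip(model.intercept + model.slope * float(entropy), 0.0, 1.0))


# ---------------------------------------------------------------------------
# policies
# ---------------------------------------------------------------------------

def restrictive_exclusion(predicted: dict, fraction: float = 0.10) -> set:
    """The ``floor(fraction * n)`` case ids with lowest predicted Dice.

    Ties are broken by case identifier for determinism.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    if not predicted:
        raise ValueError("empty cohort")
    k = int(np.floor(fraction * len(predicted)))
    ranked = sorted(predicted.items(), key=lambda kv: (kv[1], str(kv[0])))
    return {cid for cid, _ in ranked[:k]}


def qc_decide(presence_prob: float, predicted_dice_sm: float | None,
              policy: QCPolicy, in_excluded_decile: bool | None = None) -> QCDecision:
    """Combine both QC stages into one decision.

    The Dice stage is skipped when the level is judged absent. Under the
    cohort policy the caller supplies ``in_excluded_decile`` (membership in
    the lowest predicted-Dice fraction); under the absolute policy the
    threshold is applied directly.
    """
    present = presence_prob >= policy.presence_threshold
    if not present:
        return QCDecision(presence_prob=float(presence_prob), presence_flag=True,
                          predicted_dice_sm=None, excluded=True,
                          reason="absent_level")
    if policy.mode == "absolute":
        low = predicted_dice_sm is not None and predicted_dice_sm < policy.dice_threshold
    elif policy.mode == "cohort_decile":
        low = bool(in_excluded_decile)
    else:
        raise ValueError(f"unknown QC policy mode {policy.mode!r}")
    return QCDecision(presence_prob=float(presence_prob), presence_flag=False,
                      predicted_dice_sm=predicted_dice_sm, excluded=low,
                      reason="low_predicted_dice" if low else "none")
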