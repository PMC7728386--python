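"""Evaluation statistics for ddG prediction, including anti-symmetry bias.

Accuracy is summarized by the Pearson correlation r and the root-mean-square
error sigma between experimental and predicted ddG, reported separately for
direct and reverse mutations.  Bias is summarized by the correlation
r_dir_rev between paired direct and reverse predictions and by the per-pair
statistic delta = ddG_rev + ddG_dir: a perfectly anti-symmetric predictor
has r_dir_rev = -1 and delta identically zero.  The full delta vector is
always retained, because the mean <delta> alone washes out biases pointing
in opposite directions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.987e-3

#: ddG band (kcal/mol) within which stability changes are expected to be
#: fitness-neutral; boundaries inclusive.
NEUTRAL_ZONE = (-0.5, 0.5)


def pearson_r(x, y) -> float:
    """Pearson correlation coefficient between two aligned vectors."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 2:
        raise ValueError("need at least two points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(stats.pearsonr(x, y).statistic)


def rmse(x, y) -> float:
    """Root-mean-squared error of predictions ``y`` against experiments ``x``."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) == 0:
        raise ValueError("rmse of an empty vector is undefined")
    return float(np.sqrt(np.mean((y - x) ** 2)))


@dataclass
class PairedPredictions:
    """Experimental and predicted ddG for direct records and their reverses.

    All four vectors are aligned index-by-index through ``pair_ids``.
    """

    pair_ids: list[str]
    exp_dir: np.ndarray
    pred_dir: np.ndarray
    exp_rev: np.ndarray
    pred_rev: np.ndarray

    def __post_init__(self):
        n = len(self.pair_ids)
        for name in ("exp_dir", "pred_dir", "exp_rev", "pred_rev"):
            vec = np.asarray(getattr(self, name), dtype=np.float64)
            if len(vec) != n:
                raise ValueError(f"{name} has length {len(vec)}, expected {n}")
            setattr(self, name, vec)

    @classmethod
    def from_records(cls, pair_ids_dir, preds_dir, exps_dir,
                     pair_ids_rev, preds_rev, exps_rev) -> "PairedPredictions":
        """Align direct and reverse predictions by pair id."""
        rev_index = {pid: i for i, pid in enumerate(pair_ids_rev)}
        missing = [pid for pid in pair_ids_dir if pid not in rev_index]
        if missing or len(pair_ids_dir) != len(pair_ids_rev):
            raise ValueError(f"unpaired records; missing reverse ids: {missing[:5]}")
        order = [rev_index[pid] for pid in pair_ids_dir]
        return cls(
            pair_ids=list(pair_ids_dir),
            exp_dir=np.asarray(exps_dir, dtype=np.float64),
            pred_dir=np.asarray(preds_dir, dtype=np.float64),
            exp_rev=np.asarray(exps_rev, dtype=np.float64)[order],
            pred_rev=np.asarray(preds_rev, dtype=np.float64)[order],
        )


def bias_metrics(preds: PairedPredictions) -> tuple[float, np.ndarray, float]:
    """Anti-symmetry bias statistics ``(r_dir_rev, delta, mean_delta)``.

    ``delta[i] = pred_rev[i] + pred_dir[i]`` per pair; ``r_dir_rev`` is the
    Pearson correlation between the two prediction vectors.
    """
    delta = preds.pred_rev + preds.pred_dir
    r_dir_rev = pearson_r(preds.pred_dir, preds.pred_rev)
    return r_dir_rev, delta, float(delta.mean())


def error_within(x, y, thresholds=(0.5, 1.0)) -> dict[float, float]:
    """Fraction of predictions with |y - x| <= t for each threshold t."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) == 0:
        raise ValueError("empty input")
    err = np.abs(y - x)
    return {float(t): float(np.mean(err <= t)) for t in thresholds}


def neutral_fraction(ddgs) -> float:
    """Fraction of ddG values inside the neutral zone [-0.5, +0.5] kcal/mol."""
    ddgs = np.asarray(ddgs, dtype=np.float64)
    if len(ddgs) == 0:
        raise ValueError("empty input")
    lo, hi = NEUTRAL_ZONE
    return float(np.mean((ddgs >= lo) & (ddgs <= hi)))


def folding_factor(ddg: float, T: float = 310.0) -> float:
    """Multiplicative reduction of the folding equilibrium constant.

    ``exp(ddg / (R T))`` with R = 1.987e-3 kcal/(mol K); a 1 kcal/mol
    destabilization at 310 K reduces the folding equilibrium constant
    ~5.1-fold.
    """
    if T <= 0:
        raise ValueError("temperature must be positive (Kelvin)")
    return float(np.exp(ddg / (R_KCAL * T)))


@dataclass
class MetricsReport:
    """Full evaluation output for one predictor on a paired test set."""

    r_dir: float
    sigma_dir: float
    r_rev: float
    sigma_rev: float
    r_dir_rev: float
    mean_delta: float
    delta: np.ndarray
    frac_within_dir: dict[float, float]
    frac_within_rev: dict[float, float]
    neutral_fraction_pred_dir: float
    n_pairs: int = 0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "r_dir": self.r_dir,
            "sigma_dir": self.sigma_dir,
            "r_rev": self.r_rev,
            "sigma_rev": self.sigma_rev,
            "r_dir_rev": self.r_dir_rev,
            "mean_delta": self.mean_delta,
            "delta": [float(d) for d in self.delta],
            "frac_within_dir": {str(k): v for k, v in self.frac_within_dir.items()},
            "frac_within_rev": {str(k): v for k, v in self.frac_within_rev.items()},
            "neutral_fraction_pred_dir": self.neutral_fraction_pred_dir,
            "n_pairs": self.n_pairs,
            **self.extras,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def evaluate_predictions(preds: PairedPredictions,
                         thresholds=(0.5, 1.0)) -> MetricsReport:
    """Compute the standard accuracy and bias report for paired predictions."""
    r_dir_rev, delta, mean_delta = bias_metrics(preds)
    return MetricsReport(
        r_dir=pearson_r(preds.exp_dir, preds.pred_dir),
        sigma_dir=rmse(preds.exp_dir, preds.pred_dir),
        r_rev=pearson_r(preds.exp_rev, preds.pred_rev),
        sigma_rev=rmse(preds.exp_rev, preds.pred_rev),
        r_dir_rev=r_dir_rev,
        mean_delta=mean_delta,
        delta=delta,
        frac_within_dir=error_within(preds.exp_dir, preds.pred_dir, thresholds),
        frac_within_rev=error_within(preds.exp_rev, preds.pred_rev, thresholds),
        neutral_fraction_pred_dir=neutral_fraction(preds.pred_dir),
        n_pairs=len(preds.pair_ids),
    )
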