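"""The panelGC core: depth normalization, median-of-medians GC binning,
LOESS regression of depth on GC percentile, anchored fold-change scores,
AUC-difference score, and five-way bias classification.

The per-sample statistic is the relative fold-change score

    b75/25 = log2((2**b75 - 1) / (2**b25 - 1) + 1)

where b25 and b75 are the LOESS-regressed normalized depths at the AT-anchor
(default 25% GC) and GC-anchor (default 75% GC). Normalized depth is
log2(position_depth / mean_depth + 1), so a value of 1 means mean coverage,
and b75/25 == 1 means AT- and GC-rich regions are equally covered; >1 is a
GC-ward bias, <1 an AT-ward bias.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import DepthTable, ProbeSet

logger = logging.getLogger("panelgc")


class BiasClass(enum.Enum):
    AT_BIAS_FAIL = "AT_BIAS_FAIL"
    AT_BIAS_WARN = "AT_BIAS_WARN"
    NO_BIAS = "NO_BIAS"
    GC_BIAS_WARN = "GC_BIAS_WARN"
    GC_BIAS_FAIL = "GC_BIAS_FAIL"


class ScoreStatus(enum.Enum):
    SCORED = "SCORED"
    NO_COVERAGE = "NO_COVERAGE"
    UNSCORABLE = "UNSCORABLE"


@dataclass(frozen=True)
class Thresholds:
    """Classification cut-offs on the log2(ratio + 1) scale.

    Stored as exact expressions of the linear-scale fold changes they encode:
    a 2-fold relative change fails, a 1.5-fold change warns, and a 1.5-fold
    absolute deviation from mean coverage at either anchor fails.
    """

    rel_fail_hi: float = math.log2(2 + 1)        # b75/25 >= this -> GC fail
    rel_warn_hi: float = math.log2(1.5 + 1)      # b75/25 >= this -> GC warn
    rel_warn_lo: float = math.log2(1 / 1.5 + 1)  # b75/25 <= this -> AT warn
    rel_fail_lo: float = math.log2(1 / 2 + 1)    # b75/25 <= this -> AT fail
    abs_fail: float = math.log2(1.5 + 1)         # b25 or b75 >= this -> fail

    def __post_init__(self) -> None:
        if not (
            self.rel_fail_lo < self.rel_warn_lo < 1 < self.rel_warn_hi < self.rel_fail_hi
        ):
            raise ValueError("thresholds must satisfy fail_lo < warn_lo < 1 < warn_hi < fail_hi")


DEFAULT_THRESHOLDS = Thresholds()


@dataclass
class DepthProfile:
    """Per-position normalized depths of one sample over the probe union."""

    sample_id: str
    normalized: DepthTable
    mean_depth: float
    no_coverage: bool = False

    def values(self) -> np.ndarray:
        return self.normalized.values()


def normalize_depths(depths: DepthTable, sample_id: str) -> DepthProfile:
    """log2(depth / mean_depth + 1) at every probed position.

    The mean is taken over the union of probed positions (each genomic
    position counted once). A sample whose mean depth is 0 gets normalized
    depth 0 everywhere and is flagged ``no_coverage``; it is reported as
    NO_COVERAGE rather than forced into a bias class.
    """
    raw = depths.values()
    if raw.size == 0:
        raise ValueError("no probed positions: cannot normalize")
    mean_depth = float(raw.mean())
    if mean_depth == 0.0:
        logger.warning("sample %s: zero mean depth, flagged no-coverage", sample_id)
        return DepthProfile(
            sample_id,
            depths.map(lambda v: np.zeros_like(v, dtype=float)),
            0.0,
            no_coverage=True,
        )
    normalized = depths.map(lambda v: np.log2(v / mean_depth + 1.0))
    return DepthProfile(sample_id, normalized, mean_depth)


def gc_percentile(gc_fraction: float) -> int:
    """Integer GC percentile in 0-100; ties round half up."""
    return int(math.floor(gc_fraction * 100 + 0.5))


def bin_by_gc(profile: DepthProfile, probes: ProbeSet) -> pd.DataFrame:
    """Median-of-medians normalized depth per occupied GC percentile.

    Each probe's median normalized depth over its own positions is computed
    first (overlapping probes each see the shared positions); probes are then
    grouped by integer GC percentile and the median of the per-probe medians
    is taken, which resists outlier probes. Returns a DataFrame indexed by
    percentile with columns ``median_of_medians`` and ``n_probes``.
    """
    percentiles: list[int] = []
    medians: list[float] = []
    for i, probe in enumerate(probes):
        gc = probes.gc_fraction[i]
        if np.isnan(gc):
            continue
        vals = profile.normalized.probe_values(probe)
        percentiles.append(gc_percentile(gc))
        medians.append(float(np.median(vals)))
    if not percentiles:
        raise ValueError("no probe with a defined GC fraction")
    df = pd.DataFrame({"percentile": percentiles, "probe_median": medians})
    table = (
        df.groupby("percentile")["probe_median"]
        .agg(median_of_medians="median", n_probes="size")
        .sort_index()
    )
    table["n_probes"] = table["n_probes"].astype(int)
    return table


@dataclass
class BiasCurve:
    """Fitted LOESS predictor of normalized depth as a function of GC percentile."""

    x: np.ndarray          # occupied percentiles (sorted)
    y: np.ndarray          # median-of-medians at each
    span: float
    degree: int
    domain: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.domain = (int(self.x.min()), int(self.x.max()))

    def predict(self, query) -> np.ndarray:
        """Tricube-weighted local polynomial prediction (LOESS depth).

        At each query point the ``ceil(span * n)`` nearest design points get
        tricube weights on their scaled distance and a degree-``degree``
        weighted least-squares polynomial is evaluated at the point.
        """
        query = np.atleast_1d(np.asarray(query, dtype=float))
        n = len(self.x)
        q = max(self.degree + 1, int(math.ceil(self.span * n)))
        q = min(q, n)
        out = np.empty(len(query))
        for j, x0 in enumerate(query):
            d = np.abs(self.x - x0)
            idx = np.argsort(d, kind="stable")[:q]
            h = d[idx].max()
            if h == 0:
                out[j] = float(np.mean(self.y[idx]))
                continue
            w = np.clip(1 - (d[idx] / h) ** 3, 0, None) ** 3
            deg = min(self.degree, len(idx) - 1)
            X = np.vander(self.x[idx] - x0, deg + 1, increasing=True)
            Xw = X * w[:, None]
            beta, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ self.y[idx], rcond=None)
            out[j] = float(beta[0])
        return out

    def __call__(self, query) -> np.ndarray:
        return self.predict(query)


#: LOESS defaults. The span is deliberately narrow enough that a prediction
#: at one anchor is never influenced by depths on the far side of the 50% GC
#: midpoint when the percentile grid is dense; a wider window smears sharp
#: AT/GC depth transitions into both anchors and distorts the score.
DEFAULT_SPAN = 0.5
DEFAULT_DEGREE = 2
MIN_OCCUPIED_PERCENTILES = 10


def fit_bias_curve(
    table: pd.DataFrame,
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
    min_percentiles: int = MIN_OCCUPIED_PERCENTILES,
) -> BiasCurve:
    """Fit the GC-bias regression curve on (occupied percentile, value) pairs.

    Empty percentiles contribute nothing; the fit is unweighted by probe
    count. Raises when fewer than ``min_percentiles`` percentiles are
    occupied.
    """
    n = len(table)
    if n < min_percentiles:
        raise ValueError(
            f"only {n} occupied GC percentile(s); need at least {min_percentiles} to fit"
        )
    return BiasCurve(
        table.index.to_numpy(), table["median_of_medians"].to_numpy(), span, degree
    )


#: anchors at most this far outside the fit domain are clamped to the nearest
#: domain endpoint (with a warning); farther anchors make the sample unscorable
EXTRAPOLATION_MARGIN = 2


def _anchor_value(curve: BiasCurve, anchor: int) -> Optional[float]:
    lo, hi = curve.domain
    if lo <= anchor <= hi:
        return float(curve.predict(anchor)[0])
    nearest = lo if anchor < lo else hi
    if abs(anchor - nearest) <= EXTRAPOLATION_MARGIN:
        logger.warning(
            "anchor %d outside fit domain [%d, %d]; using endpoint %d",
            anchor, lo, hi, nearest,
        )
        return float(curve.predict(nearest)[0])
    logger.warning(
        "anchor %d too far outside fit domain [%d, %d]; sample unscorable",
        anchor, lo, hi,
    )
    return None


def relative_fold_change(b25: float, b75: float) -> float:
    """b75/25 = log2((2^b75 - 1)/(2^b25 - 1) + 1), with sentinel handling.

    The back-transformed (linear-scale) depth at an anchor is 2^b - 1. A zero
    or negative linear depth at the AT anchor makes the ratio blow up: +inf
    sentinel. At the GC anchor the score floors at log2(0 + 1) = 0.
    """
    lin25 = 2.0 ** b25 - 1.0
    lin75 = 2.0 ** b75 - 1.0
    if lin25 <= 0.0:
        return math.inf
    if lin75 <= 0.0:
        return 0.0
    return math.log2(lin75 / lin25 + 1.0)


@dataclass
class BiasScores:
    """Per-sample bias scores and their classification."""

    sample_id: str
    b25: Optional[float]
    b75: Optional[float]
    b75_25: Optional[float]
    auc_diff: Optional[float]
    bias_class: Optional[BiasClass]
    status: ScoreStatus = ScoreStatus.SCORED
    at_anchor: int = 25
    gc_anchor: int = 75
    n_probes_used: int = 0
    mean_depth: float = 0.0
    notes: list[str] = field(default_factory=list)


def score_bias(
    curve: BiasCurve, at_anchor: int = 25, gc_anchor: int = 75
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """LOESS depths at the anchors and the relative fold-change score.

    Returns ``(b25, b75, b75_25)``; any of them is None when the anchor is
    too far outside the fit domain.
    """
    if not 0 <= at_anchor < gc_anchor <= 100:
        raise ValueError("anchors must satisfy 0 <= at_anchor < gc_anchor <= 100")
    b25 = _anchor_value(curve, at_anchor)
    b75 = _anchor_value(curve, gc_anchor)
    if b25 is None or b75 is None:
        return b25, b75, None
    return b25, b75, relative_fold_change(b25, b75)


def score_auc(curve: BiasCurve) -> Optional[float]:
    """AUC-difference score: sum of LOESS depths at integer percentiles >=50
    minus the sum at percentiles <50, restricted to the fit domain.

    Undefined (None) when the fit domain lies entirely on one side of 50.
    This score is reported for inspection but never drives classification.
    """
    lo, hi = curve.domain
    if hi < 50 or lo >= 50:
        return None
    below = np.arange(lo, 50)
    above = np.arange(50, hi + 1)
    return float(curve.predict(above).sum() - curve.predict(below).sum())


def classify_bias(
    b25: float,
    b75: float,
    b75_25: float,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> tuple[BiasClass, list[str]]:
    """Five-way classification; failures take precedence over warnings.

    GC fail: b75/25 >= rel_fail_hi or b75 >= abs_fail.
    AT fail: b75/25 <= rel_fail_lo or b25 >= abs_fail.
    If both absolute fail conditions hold at once, the direction of b75/25
    relative to 1 breaks the tie and a bidirectional-anomaly note is attached.
    Returns the class plus any notes.
    """
    notes: list[str] = []
    gc_fail = b75_25 >= thresholds.rel_fail_hi or b75 >= thresholds.abs_fail
    at_fail = b75_25 <= thresholds.rel_fail_lo or b25 >= thresholds.abs_fail
    if gc_fail and at_fail:
        notes.append("bidirectional anomaly: both anchors deviate from mean coverage")
        return (
            BiasClass.GC_BIAS_FAIL if b75_25 >= 1 else BiasClass.AT_BIAS_FAIL,
            notes,
        )
    if gc_fail:
        return BiasClass.GC_BIAS_FAIL, notes
    if at_fail:
        return BiasClass.AT_BIAS_FAIL, notes
    if thresholds.rel_warn_hi <= b75_25 < thresholds.rel_fail_hi:
        return BiasClass.GC_BIAS_WARN, notes
    if thresholds.rel_fail_lo < b75_25 <= thresholds.rel_warn_lo:
        return BiasClass.AT_BIAS_WARN, notes
    return BiasClass.NO_BIAS, notes


def score_sample(
    depths: DepthTable,
    probes: ProbeSet,
    sample_id: str,
    at_anchor: int = 25,
    gc_anchor: int = 75,
    span: float = DEFAULT_SPAN,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> tuple[BiasScores, Optional[BiasCurve]]:
    """Full per-sample pipeline: normalize, bin, fit, score, classify.

    Returns the scores and the fitted curve (None when the sample has no
    coverage). Zero-coverage samples get status NO_COVERAGE and no scores;
    samples whose anchors are unreachable get status UNSCORABLE.
    """
    profile = normalize_depths(depths, sample_id)
    n_usable = int(probes.usable.sum())
    if profile.no_coverage:
        return (
            BiasScores(
                sample_id, None, None, None, None, None,
                status=ScoreStatus.NO_COVERAGE,
                at_anchor=at_anchor, gc_anchor=gc_anchor,
                n_probes_used=n_usable, mean_depth=0.0,
                notes=["no coverage on probed positions"],
            ),
            None,
        )
    table = bin_by_gc(profile, probes)
    curve = fit_bias_curve(table, span=span)
    b25, b75, b75_25 = score_bias(curve, at_anchor, gc_anchor)
    auc = score_auc(curve)
    if b75_25 is None:
        return (
            BiasScores(
                sample_id, b25, b75, None, auc, None,
                status=ScoreStatus.UNSCORABLE,
                at_anchor=at_anchor, gc_anchor=gc_anchor,
                n_probes_used=n_usable, mean_depth=profile.mean_depth,
                notes=["anchor outside LOESS fit domain"],
            ),
            curve,
        )
    notes: list[str] = []
    if math.isinf(b75_25):
        bias_class = BiasClass.GC_BIAS_FAIL
        notes.append("zero linear-scale depth at AT anchor")
    elif b75_25 == 0.0 and 2.0 ** b75 - 1.0 <= 0.0:
        bias_class = BiasClass.AT_BIAS_FAIL
        notes.append("zero linear-scale depth at GC anchor")
    else:
        bias_class, notes = classify_bias(b25, b75, b75_25, thresholds)
    return (
        BiasScores(
            sample_id, b25, b75, b75_25, auc, bias_class,
            status=ScoreStatus.SCORED,
            at_anchor=at_anchor, gc_anchor=gc_anchor,
            n_probes_used=n_usable, mean_depth=profile.mean_depth,
            notes=notes,
        ),
        curve,
    )


def scores_to_frame(scores: list[BiasScores]) -> pd.DataFrame:
    """Tabulate per-sample scores for export (one row per sample)."""
    rows = []
    for s in scores:
        rows.append(
            {
                "sample_id": s.sample_id,
                "b25": s.b25,
                "b75": s.b75,
                "b75_25": s.b75_25,
                "auc_diff": s.auc_diff,
                "bias_class": s.bias_class.value if s.bias_class else s.status.value,
                "status": s.status.value,
                "n_probes_used": s.n_probes_used,
                "mean_depth": s.mean_depth,
                "notes": ";".join(s.notes),
            }
        )
    return pd.DataFrame(rows)
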