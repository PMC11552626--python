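"""Frequency of known modification sites near candidate sites, and a
coarse classifier for the shape of that frequency profile."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .alphabet import LabelChannel
from .datasets import SiteRecord


class ProximityError(ValueError):
    pass


# classification thresholds (declared constants; diagnostics always reported)
CV_UNIFORM_MAX = 0.15
AUTOCORR_MIN = 0.4
SPEARMAN_DECAY_MAX = -0.5
DETREND_WINDOW = 5


@dataclass
class ProximityHistogram:
    """Counts of known sites at each signed offset from candidate sites.

    Offsets run ``-w .. +w`` with 0 (the candidate itself) excluded;
    N-terminal offsets are negative.  ``normalized`` divides by the number
    of candidate sites so histograms are comparable across datasets.
    """

    offsets: np.ndarray
    counts: np.ndarray
    n_candidates: int
    stratum: str = "all"

    @property
    def normalized(self) -> np.ndarray:
        if self.n_candidates == 0:
            return np.zeros_like(self.counts, dtype=np.float64)
        return self.counts / self.n_candidates

    @property
    def w(self) -> int:
        return int(self.offsets.max())


def nearby_ptm_frequency(
    records: list[SiteRecord],
    channel: LabelChannel,
    w: int = 26,
    *,
    stratum: str = "all",
) -> ProximityHistogram:
    """Count labeled sites at offsets -w..+w (excluding 0) from each record.

    ``stratum`` selects which candidates contribute: ``"all"``, ``"pos"``
    (modified candidates only) or ``"neg"``.
    """
    if w < 1:
        raise ProximityError(f"window half-width must be >= 1, got {w}")
    if stratum not in ("all", "pos", "neg"):
        raise ProximityError(f"unknown stratum {stratum!r}")
    offsets = np.array([d for d in range(-w, w + 1) if d != 0])
    counts = np.zeros(len(offsets), dtype=np.int64)
    col = {d: i for i, d in enumerate(offsets.tolist())}

    selected = [
        r for r in records
        if stratum == "all"
        or (stratum == "pos" and r.label == 1)
        or (stratum == "neg" and r.label == 0)
    ]
    for r in selected:
        sites = channel.sites_for(r.protein_id)
        if not sites:
            continue
        for d in offsets.tolist():
            if r.position + d in sites:
                counts[col[d]] += 1
    return ProximityHistogram(
        offsets=offsets, counts=counts, n_candidates=len(selected), stratum=stratum
    )


@dataclass
class PatternDiagnostics:
    cv: float
    best_period: int
    autocorr_peak: float
    autocorr_z: float
    spearman_rho: float

    def to_dict(self) -> dict:
        return {
            "cv": self.cv,
            "best_period": self.best_period,
            "autocorr_peak": self.autocorr_peak,
            "autocorr_z": self.autocorr_z,
            "spearman_rho": self.spearman_rho,
        }


def _autocorrelation(c: np.ndarray, max_lag: int) -> np.ndarray:
    """Normalized autocorrelation of *detrended* counts for lags 2..max_lag.

    A centered moving average is subtracted first so that smooth (e.g.
    monotonically decaying) profiles do not register as periodic; only
    repetitive structure faster than the trend window survives.
    """
    from scipy.ndimage import uniform_filter1d

    resid = c - uniform_filter1d(c, size=DETREND_WINDOW, mode="nearest")
    x = resid - resid.mean()
    denom = float(x @ x)
    if denom == 0.0:
        return np.zeros(max(0, max_lag - 1))
    return np.array(
        [float(x[:-lag] @ x[lag:]) / denom for lag in range(2, max_lag + 1)]
    )


def classify_pattern(
    hist: ProximityHistogram,
) -> tuple[str, PatternDiagnostics]:
    """Label the histogram shape: ``periodic``, ``decaying`` or ``uniform``.

    Diagnostics: coefficient of variation across offsets (uniformity),
    autocorrelation peak over lags >= 2 (periodicity; the peak lag is the
    reported period), and Spearman correlation of count against |offset|
    (decay).  Precedence when several fire: periodic > decaying > uniform.
    The label is a convenience; the diagnostics are always returned so the
    call is auditable.
    """
    counts = hist.counts.astype(np.float64)
    if counts.sum() == 0:
        raise ProximityError("all-zero histogram cannot be classified")

    cv = float(counts.std() / counts.mean())

    max_lag = max(2, len(counts) // 4)
    ac = _autocorrelation(counts, max_lag)
    if ac.size:
        peak_i = int(np.argmax(ac))
        best_period = peak_i + 2
        autocorr_peak = float(ac[peak_i])
        spread = float(ac.std())
        autocorr_z = (autocorr_peak - float(ac.mean())) / spread if spread > 0 else 0.0
    else:
        best_period, autocorr_peak, autocorr_z = 0, 0.0, 0.0

    if np.ptp(counts) == 0:
        rho = 0.0  # constant counts: no rank trend
    else:
        rho = stats.spearmanr(np.abs(hist.offsets), counts).statistic
        rho = float(rho) if np.isfinite(rho) else 0.0

    diag = PatternDiagnostics(
        cv=cv,
        best_period=best_period,
        autocorr_peak=autocorr_peak,
        autocorr_z=autocorr_z,
        spearman_rho=rho,
    )
    if autocorr_peak >= AUTOCORR_MIN:
        return "periodic", diag
    if rho <= SPEARMAN_DECAY_MAX:
        return "decaying", diag
    return "uniform", diag
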