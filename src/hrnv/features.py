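"""Time-domain, frequency-domain and nonlinear parameters of RR sequences.

Each derived stream (HRV, HR2V, HR2V1, HR3V, HR3V1, HR3V2) gets the same
parameter suite:

* time domain — Mean NN, SDNN, RMSSD, skewness, kurtosis, triangular index,
  NN50/pNN50 and, for aggregated streams (n >= 2), NN50n/pNN50n with the
  threshold scaled to 50·n ms;
* frequency domain — VLF/LF/HF band powers (ms²) of the unevenly sampled
  tachogram via the Lomb–Scargle periodogram, normalised LF/HF powers and
  the LF/HF ratio;
* nonlinear — Poincaré SD1/SD2, sample and approximate entropy, and the
  short- and long-range detrended-fluctuation exponents α1/α2.

Missing or undefined parameters are reported as NaN, never silently zero.
The full per-patient vector over all six streams has 142 named entries
(22 for HRV, which has no NN50n/pNN50n, and 24 for each of the five
aggregated streams).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.spatial.distance import cdist

from .rr import DerivedRRSequence, RRSeries, enumerate_streams, stream_label

__all__ = [
    "PARAM_NAMES",
    "STREAM_PREFIXES",
    "FEATURE_NAMES",
    "time_domain",
    "frequency_domain",
    "poincare",
    "entropy",
    "dfa",
    "dfa_fluctuations",
    "feature_vector",
    "feature_table",
    "VLF_BAND",
    "LF_BAND",
    "HF_BAND",
]

# Parameter order mirrors the conventional reporting grid.
PARAM_NAMES: tuple[str, ...] = (
    "mean_nn", "sdnn", "rmssd", "skewness", "kurtosis", "triangular_index",
    "nn50", "pnn50", "nn50n", "pnn50n",
    "total_power", "vlf", "lf", "hf", "lf_norm", "hf_norm", "lf_hf",
    "sd1", "sd2", "sd1_sd2", "sampen", "apen", "dfa_a1", "dfa_a2",
)
# The n=1 stream has no scaled-threshold counts.
_HRV_EXCLUDED = ("nn50n", "pnn50n")

STREAM_PREFIXES: tuple[str, ...] = ("hrv", "hr2v", "hr2v1", "hr3v", "hr3v1", "hr3v2")

# Standard short-term HRV bands (Hz).
VLF_BAND = (0.003, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)

_TRI_BIN_MS = 1000.0 / 128.0  # conventional 1/128 s histogram discretisation


def _stream_params(prefix: str) -> tuple[str, ...]:
    if prefix == "hrv":
        return tuple(p for p in PARAM_NAMES if p not in _HRV_EXCLUDED)
    return PARAM_NAMES


FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{prefix}_{param}" for prefix in STREAM_PREFIXES for param in _stream_params(prefix)
)


class InsufficientDataError(ValueError):
    """Raised when a sequence is too short for the requested parameter family."""


# ---------------------------------------------------------------------------
# Time domain
# ---------------------------------------------------------------------------

def time_domain(seq: DerivedRRSequence) -> dict[str, float]:
    """Mean NN, SDNN, RMSSD, shape moments, triangular index and NN50 counts.

    For aggregated streams (n >= 2) the NN50n/pNN50n pair uses the scaled
    threshold 50·n ms.  pNN50-type proportions are percentages of the number
    of successive differences.
    """
    x = seq.values
    if x.size < 3:
        raise InsufficientDataError(
            f"time-domain parameters need >= 3 values, got {x.size}"
        )
    d = np.diff(x)
    out: dict[str, float] = {
        "mean_nn": float(np.mean(x)),
        "sdnn": float(np.std(x, ddof=1)),
        "rmssd": float(np.sqrt(np.mean(d**2))),
    }
    if out["sdnn"] > 0:
        out["skewness"] = float(stats.skew(x, bias=True))
        out["kurtosis"] = float(stats.kurtosis(x, fisher=False, bias=True))
    else:
        out["skewness"] = np.nan
        out["kurtosis"] = np.nan
    # Triangular index: N over the modal bin count of the 1/128 s histogram.
    lo = np.floor(x.min() / _TRI_BIN_MS) * _TRI_BIN_MS
    edges = np.arange(lo, x.max() + _TRI_BIN_MS, _TRI_BIN_MS)
    if edges.size < 2:
        edges = np.array([lo, lo + _TRI_BIN_MS])
    counts, _ = np.histogram(x, bins=edges)
    out["triangular_index"] = float(x.size / counts.max())
    nn50 = int(np.sum(np.abs(d) > 50.0))
    out["nn50"] = float(nn50)
    out["pnn50"] = 100.0 * nn50 / d.size
    if seq.n >= 2:
        nn50n = int(np.sum(np.abs(d) > 50.0 * seq.n))
        out["nn50n"] = float(nn50n)
        out["pnn50n"] = 100.0 * nn50n / d.size
    return out


# ---------------------------------------------------------------------------
# Frequency domain
# ---------------------------------------------------------------------------

def _lomb_scargle(t: np.ndarray, y: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Classical Lomb periodogram with the phase correction tau, vectorized
    over frequencies (equivalent to scipy.signal.lombscargle on centred data)."""
    w = (2.0 * np.pi * freqs)[:, None]
    wt = w * t[None, :]
    tau = np.arctan2(np.sin(2 * wt).sum(axis=1), np.cos(2 * wt).sum(axis=1)) / 2.0
    arg = wt - tau[:, None]
    c, s = np.cos(arg), np.sin(arg)
    yc, ys = c @ y, s @ y
    cc, ss = (c * c).sum(axis=1), (s * s).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 0.5 * (np.where(cc > 0, yc**2 / cc, 0.0)
                   + np.where(ss > 0, ys**2 / ss, 0.0))
    return p


def frequency_domain(seq: DerivedRRSequence) -> dict[str, float]:
    """Band powers of the tachogram via the Lomb–Scargle periodogram.

    Beat times are cumulative sums of the sequence values (seconds); no
    resampling is applied.  The periodogram is scaled so that its integral
    over the evaluated grid equals the series variance, making band powers
    absolute (ms²).  total_power = VLF + LF + HF by construction.
    """
    x = seq.values
    if x.size < 16:
        raise InsufficientDataError(
            f"frequency-domain parameters need >= 16 values, got {x.size}"
        )
    t = np.cumsum(x) / 1000.0  # beat times in s
    if t[-1] - t[0] < 60.0:
        raise InsufficientDataError(
            f"frequency-domain parameters need >= 60 s of data, got {t[-1] - t[0]:.1f} s"
        )
    y = x - x.mean()
    var = float(np.var(y))
    zero = {"total_power": 0.0, "vlf": 0.0, "lf": 0.0, "hf": 0.0,
            "lf_norm": np.nan, "hf_norm": np.nan, "lf_hf": np.nan}
    if var == 0.0:
        return zero
    span = t[-1] - t[0]
    df = 1.0 / (4.0 * span)  # 4x oversampling of the natural resolution
    f_max = 0.5 * (x.size - 1) / span  # mean Nyquist of the uneven sampling
    freqs = np.arange(df, max(f_max, HF_BAND[1]) + df, df)
    pgram = _lomb_scargle(t, y, freqs)
    total = pgram.sum() * df
    if total <= 0:
        return zero
    psd = pgram * (var / total)  # ms^2 per Hz over the evaluated grid

    def band_power(lo: float, hi: float) -> float:
        sel = (freqs >= lo) & (freqs < hi)
        return float(psd[sel].sum() * df)

    vlf = band_power(*VLF_BAND)
    lf = band_power(*LF_BAND)
    hf = band_power(*HF_BAND)
    out = {"total_power": vlf + lf + hf, "vlf": vlf, "lf": lf, "hf": hf}
    if lf + hf > 0:
        out["lf_norm"] = 100.0 * lf / (lf + hf)
        out["hf_norm"] = 100.0 * hf / (lf + hf)
    else:
        out["lf_norm"] = np.nan
        out["hf_norm"] = np.nan
    out["lf_hf"] = lf / hf if hf > 0 else np.nan
    return out


# ---------------------------------------------------------------------------
# Poincaré geometry
# ---------------------------------------------------------------------------

def poincare(seq: DerivedRRSequence) -> dict[str, float]:
    """SD1/SD2 dispersions of the lag-1 return map.

    SD1/SD2 are population dispersions of the rotated coordinates
    (x_{k+1} − x_k)/√2 and (x_{k+1} + x_k)/√2, which makes SD1 agree with
    RMSSD/√2 up to the (negligible) mean successive difference.
    """
    x = seq.values
    if x.size < 3:
        raise InsufficientDataError(f"Poincaré parameters need >= 3 values, got {x.size}")
    a, b = x[:-1], x[1:]
    sd1 = float(np.std((b - a) / np.sqrt(2.0), ddof=0))
    sd2 = float(np.std((b + a) / np.sqrt(2.0), ddof=0))
    return {"sd1": sd1, "sd2": sd2, "sd1_sd2": sd1 / sd2 if sd2 > 0 else np.nan}


# ---------------------------------------------------------------------------
# Entropy (template matching with Chebyshev tolerance r)
# ---------------------------------------------------------------------------

def _template_matrix(x: np.ndarray, m: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(x, m)


def entropy(seq: DerivedRRSequence, m: int = 2, r_frac: float = 0.2) -> tuple[float, float]:
    """(SampEn, ApEn) with embedding dimension m and tolerance r = r_frac · SD.

    SampEn = −ln(A/B) over the N−m templates of lengths m and m+1, pairs
    counted once and self-matches excluded.  ApEn = Φ_m − Φ_{m+1} with
    self-matches included.  SampEn is NaN when no template pair matches.
    """
    x = np.asarray(seq.values, dtype=float)
    N = x.size
    if N < 20:
        raise InsufficientDataError(f"entropy needs >= 20 values, got {N}")
    r = r_frac * np.std(x, ddof=1)

    def pair_count(k: int) -> int:
        # matched (i<j) template pairs of length k among the first N-m templates
        tm = _template_matrix(x, k)[: N - m]
        dist = cdist(tm, tm, metric="chebyshev")
        return int(np.sum(np.triu(dist <= r, k=1)))

    B = pair_count(m)
    A = pair_count(m + 1)
    sampen = -np.log(A / B) if A > 0 and B > 0 else np.nan

    def phi(k: int) -> float:
        tm = _template_matrix(x, k)
        dist = cdist(tm, tm, metric="chebyshev")
        c = np.sum(dist <= r, axis=1) / tm.shape[0]
        return float(np.mean(np.log(c)))

    apen = phi(m) - phi(m + 1)
    return float(sampen) if np.isfinite(sampen) else np.nan, float(apen)


# ---------------------------------------------------------------------------
# Detrended fluctuation analysis
# ---------------------------------------------------------------------------

def dfa_fluctuations(values: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """RMS fluctuation F(s) of the integrated, first-order-detrended profile."""
    x = np.asarray(values, dtype=float)
    y = np.cumsum(x - x.mean())
    out = np.empty(len(sizes))
    for i, s in enumerate(sizes):
        k = y.size // s
        seg = y[: k * s].reshape(k, s)
        t = np.arange(s, dtype=float)
        # least-squares line per box
        tc = t - t.mean()
        slope = seg @ tc / (tc @ tc)
        resid = seg - seg.mean(axis=1, keepdims=True) - slope[:, None] * tc
        out[i] = np.sqrt(np.mean(resid**2))
    return out


def _dfa_exponent(values: np.ndarray, lo: int, hi: int) -> float:
    n = len(values)
    hi = min(hi, n // 2)  # need at least two complete boxes
    sizes = np.unique(np.round(np.geomspace(lo, hi, num=10)).astype(int))
    sizes = sizes[(sizes >= lo) & (sizes <= hi)]
    if sizes.size < 3:
        return np.nan
    F = dfa_fluctuations(values, sizes)
    if np.any(F <= 0):
        return np.nan
    slope, _ = np.polyfit(np.log(sizes), np.log(F), 1)
    return float(slope)


def dfa(seq: DerivedRRSequence) -> tuple[float, float]:
    """Short- (α1, boxes 4–16) and long-range (α2, boxes 16–64) scaling exponents.

    α1 requires >= 30 values, α2 >= 100; otherwise the affected exponent is NaN.
    """
    x = seq.values
    a1 = _dfa_exponent(x, 4, 16) if x.size >= 30 else np.nan
    a2 = _dfa_exponent(x, 16, 64) if x.size >= 100 else np.nan
    return a1, a2


# ---------------------------------------------------------------------------
# Per-patient feature vector
# ---------------------------------------------------------------------------

def _stream_features(seq: DerivedRRSequence) -> dict[str, float]:
    prefix = seq.stream_label.lower()
    params = {p: np.nan for p in _stream_params(prefix)}
    for fn in (time_domain, frequency_domain, poincare):
        try:
            params.update({k: v for k, v in fn(seq).items() if k in params})
        except InsufficientDataError:
            pass
    try:
        params["sampen"], params["apen"] = entropy(seq)
    except InsufficientDataError:
        pass
    params["dfa_a1"], params["dfa_a2"] = dfa(seq)
    return {f"{prefix}_{k}": v for k, v in params.items()}


def feature_vector(rr: RRSeries) -> pd.Series:
    """All 142 stream features for one patient, in the fixed registry order.

    Streams failing their length preconditions contribute NaN entries; the
    vector is always complete and identically named across patients.
    """
    feats: dict[str, float] = {}
    for seq in enumerate_streams(rr, max_n=3):
        feats.update(_stream_features(seq))
    return pd.Series([feats.get(name, np.nan) for name in FEATURE_NAMES],
                     index=list(FEATURE_NAMES), name=rr.patient_id, dtype=float)


def feature_table(series: list[RRSeries]) -> pd.DataFrame:
    """Stack per-patient feature vectors into a patients × features table."""
    df = pd.DataFrame([feature_vector(rr) for rr in series])
    df.index.name = "patient_id"
    return df
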