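"""The 94-metric HRV panel: temporal, frequency, complexity and specialized
domains, with a registry mapping every metric to its domain.

Domain census: 25 temporal, 6 frequency, 54 complexity/information,
9 specialized.  Metrics explicitly named in the study protocol carry
``inferred=False``; the remaining slots are filled with documented,
conventional variants (percentile indices, SDNN-index segments, multiscale
entropy scales 1-10, MFDFA h(q) for q = -5..5, lagged/derived Poincare and
fractal variants) and are tagged ``inferred_panel_member`` so their
provenance is explicit.

All metrics are computed on the NN series (artifact-flagged beats removed)
except the entropy rate, which is computed on the smoothed uniform HR
signal.  Per-metric failures are isolated: a failed metric becomes a
missing value with a reason code, never an aborted vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.signal import lombscargle

from . import entropy_core
from .signal_prep import RRSeries, UniformHRSeries

logger = logging.getLogger(__name__)

__all__ = [
    "METRIC_REGISTRY",
    "MetricSpec",
    "MetricVector",
    "compute_time_domain",
    "compute_frequency_domain",
    "compute_complexity_domain",
    "compute_specialized",
    "compute_all",
    "battery_matrix",
    "flag_outliers",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)
TP_BAND = (0.0033, 0.4)  # lower edge above 1/600 Hz for a 10-min window
HTI_BIN_MS = 7.8125


@dataclass(frozen=True)
class MetricSpec:
    domain: str  # temporal | frequency | complexity | specialized
    units: str
    description: str
    inferred: bool = False  # True -> inferred_panel_member


def _registry() -> dict[str, MetricSpec]:
    r: dict[str, MetricSpec] = {}

    def add(name, domain, units, desc, inferred=False):
        r[name] = MetricSpec(domain, units, desc, inferred)

    # ---- temporal (25) -------------------------------------------------
    add("mean_nn", "temporal", "ms", "mean NN interval")
    add("median_nn", "temporal", "ms", "median NN interval", True)
    add("min_nn", "temporal", "ms", "minimum NN interval", True)
    add("max_nn", "temporal", "ms", "maximum NN interval", True)
    add("range_nn", "temporal", "ms", "max - min NN interval", True)
    add("sdnn", "temporal", "ms", "SD of NN intervals")
    add("rmssd", "temporal", "ms", "root-mean-square of successive differences")
    add("sdsd", "temporal", "ms", "SD of successive differences", True)
    add("cvnn", "temporal", "ratio", "SDNN / mean NN")
    add("cvsd", "temporal", "ratio", "RMSSD / mean NN", True)
    add("pnn50", "temporal", "%", "% successive diffs > 50 ms")
    add("pnn20", "temporal", "%", "% successive diffs > 20 ms")
    for mins in (1, 2, 5):
        add(f"sdann_{mins}", "temporal", "ms",
            f"SD of {mins}-min segment means")
        add(f"sdnni_{mins}", "temporal", "ms",
            f"mean of {mins}-min segment SDs", True)
    for p in (5, 25, 75, 95):
        add(f"prc{p}_nn", "temporal", "ms", f"{p}th percentile of NN", True)
    add("iqr_nn", "temporal", "ms", "interquartile range of NN", True)
    add("hti", "temporal", "ratio", "HRV triangular index (7.8125 ms bins)")
    add("tinn", "temporal", "ms", "triangular interpolation base width")

    # ---- frequency (6) -------------------------------------------------
    add("lf_power", "frequency", "ms2", "power 0.04-0.15 Hz (Lomb-Scargle)")
    add("hf_power", "frequency", "ms2", "power 0.15-0.4 Hz (Lomb-Scargle)")
    add("total_power", "frequency", "ms2", "power 0-0.4 Hz (Lomb-Scargle)")
    add("lf_hf_ratio", "frequency", "ratio", "LF / HF power")
    add("lfnu", "frequency", "%", "LF / (LF + HF) x 100")
    add("hfnu", "frequency", "%", "HF / (LF + HF) x 100")

    # ---- complexity / information (54) ---------------------------------
    add("sd1", "complexity", "ms", "Poincare short-axis SD")
    add("sd2", "complexity", "ms", "Poincare long-axis SD")
    add("sd1_sd2_ratio", "complexity", "ratio", "SD1 / SD2", True)
    add("ellipse_area", "complexity", "ms2", "pi SD1 SD2 Poincare area", True)
    add("csi", "complexity", "ratio", "cardiac sympathetic index SD2/SD1")
    add("cvi", "complexity", "log10(ms2)", "cardiac vagal index log10(16 SD1 SD2)")
    add("csi_modified", "complexity", "ms", "modified CSI = SD2^2 / SD1", True)
    add("apen", "complexity", "nats", "approximate entropy m=2, r=0.2 SD")
    add("apen_m3", "complexity", "nats", "approximate entropy m=3", True)
    add("sampen", "complexity", "nats", "sample entropy m=2, r=0.2 SD")
    add("sampen_m3", "complexity", "nats", "sample entropy m=3", True)
    add("fuzzy_entropy", "complexity", "nats", "fuzzy entropy m=2, exp membership")
    add("fuzzy_entropy_m3", "complexity", "nats", "fuzzy entropy m=3", True)
    add("shannon_entropy", "complexity", "nats", "histogram Shannon entropy")
    add("renyi_entropy_2", "complexity", "nats", "collision (Renyi-2) entropy", True)
    add("perm_entropy_3", "complexity", "ratio", "permutation entropy order 3", True)
    add("perm_entropy_4", "complexity", "ratio", "permutation entropy order 4", True)
    add("entropy_rate", "complexity", "nats",
        "k-NN conditional differential entropy of smoothed HR at lag tau")
    for s in range(1, 11):
        add(f"mse_{s}", "complexity", "nats",
            f"multiscale sample entropy, scale {s}", s > 1)
    add("mse_area", "complexity", "nats", "sum of MSE over scales 1-10", True)
    add("mse_slope", "complexity", "nats/scale", "slope of MSE over scales", True)
    add("dfa_alpha1", "complexity", "exponent", "DFA scaling, scales 4-16")
    add("dfa_alpha2", "complexity", "exponent", "DFA scaling, scales 16-64")
    add("dfa_alpha_full", "complexity", "exponent", "DFA scaling, scales 4-64", True)
    for q in range(-5, 6):
        tag = f"qm{-q}" if q < 0 else f"qp{q}"
        add(f"mfdfa_h_{tag}", "complexity", "exponent",
            f"MFDFA generalized Hurst exponent h(q={q})", q != 2)
    add("mfdfa_width", "complexity", "exponent",
        "h(-5) - h(5) multifractal width", True)
    add("correlation_dim", "complexity", "dimension",
        "Grassberger-Procaccia correlation dimension, embedding 2")
    add("correlation_dim_emb3", "complexity", "dimension",
        "correlation dimension, embedding 3", True)
    add("higuchi_fd", "complexity", "dimension", "Higuchi fractal dim, kmax=10")
    add("higuchi_fd_kmax20", "complexity", "dimension",
        "Higuchi fractal dim, kmax=20", True)
    add("katz_fd", "complexity", "dimension", "Katz fractal dimension")
    add("petrosian_fd", "complexity", "dimension", "Petrosian fractal dimension", True)
    add("lzc", "complexity", "ratio", "Lempel-Ziv complexity, median-binarized")
    add("lzc_3bin", "complexity", "ratio", "Lempel-Ziv complexity, tertile-coded", True)
    add("hurst_rs", "complexity", "exponent", "rescaled-range Hurst exponent", True)

    # ---- specialized (9) -----------------------------------------------
    add("hrt_onset", "specialized", "%", "heart-rate turbulence onset (Schmidt)")
    add("hrt_slope", "specialized", "ms/beat", "heart-rate turbulence slope (Schmidt)")
    add("cv_percent", "specialized", "%", "coefficient of variation SDNN/meanNN x 100")
    add("madnn", "specialized", "ms", "median absolute deviation of NN", True)
    add("mcvnn", "specialized", "ratio", "MAD / median NN", True)
    add("trend_slope", "specialized", "ms/min", "linear drift of NN over the window", True)
    add("centroid_freq", "specialized", "Hz", "power-weighted mean frequency 0-0.4 Hz")
    add("freq_bandwidth", "specialized", "Hz", "power-weighted SD of frequency")
    add("spectral_entropy", "specialized", "ratio",
        "normalized Shannon entropy of the 0-0.4 Hz spectrum", True)
    return r


METRIC_REGISTRY: dict[str, MetricSpec] = _registry()

_counts = pd.Series([s.domain for s in METRIC_REGISTRY.values()]).value_counts()
assert len(METRIC_REGISTRY) == 94, len(METRIC_REGISTRY)
assert (_counts["temporal"], _counts["frequency"],
        _counts["complexity"], _counts["specialized"]) == (25, 6, 54, 9), _counts


@dataclass
class MetricVector:
    """One window's 94 metric values; missing entries carry a reason code."""

    subject: str
    visit: str
    position: str
    values: dict = field(default_factory=dict)
    reasons: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(METRIC_REGISTRY) - set(self.values)
        extra = set(self.values) - set(METRIC_REGISTRY)
        if missing or extra:
            raise ValueError(f"keys must match registry (missing={missing}, "
                             f"extra={extra})")

    def n_defined(self) -> int:
        return int(np.sum([np.isfinite(v) for v in self.values.values()]))


def _nn(rr: RRSeries) -> tuple[np.ndarray, np.ndarray]:
    """Normal-to-normal intervals: artifact-flagged beats removed."""
    keep = ~rr.artifact_flags
    return rr.beat_times[keep], rr.rr[keep]


# --------------------------------------------------------------------------
# temporal domain
# --------------------------------------------------------------------------

def _tinn(nn: np.ndarray) -> float:
    """Base width of the best-fitting triangle on the NN histogram."""
    lo = np.floor(nn.min() / HTI_BIN_MS) * HTI_BIN_MS
    hi = np.ceil(nn.max() / HTI_BIN_MS) * HTI_BIN_MS + HTI_BIN_MS
    edges = np.arange(lo, hi + HTI_BIN_MS / 2, HTI_BIN_MS)
    hist, edges = np.histogram(nn, bins=edges)
    if hist.size < 3:
        return float(edges[-1] - edges[0])
    peak = int(np.argmax(hist))
    centers = (edges[:-1] + edges[1:]) / 2
    best = (np.inf, 0.0)
    for i in range(0, peak + 1):
        for j in range(peak, hist.size):
            if j - i < 1:
                continue
            tri = np.zeros_like(hist, dtype=float)
            left = np.arange(i, peak + 1)
            if peak > i:
                tri[left] = hist[peak] * (left - i) / (peak - i)
            else:
                tri[peak] = hist[peak]
            right = np.arange(peak, j + 1)
            if j > peak:
                tri[right] = hist[peak] * (j - right) / (j - peak)
            tri[peak] = hist[peak]
            err = float(np.sum((hist - tri) ** 2))
            if err < best[0]:
                best = (err, centers[j] - centers[i])
    return float(best[1])


def compute_time_domain(rr: RRSeries) -> tuple[dict, dict]:
    """The 25 temporal metrics.  Returns (values, reasons)."""
    t, nn = _nn(rr)
    vals: dict = {}
    reasons: dict = {}
    names = [k for k, s in METRIC_REGISTRY.items() if s.domain == "temporal"]
    for k in names:
        vals[k] = np.nan
    if nn.size < 2:
        for k in names:
            reasons[k] = "fewer than 2 NN intervals"
        return vals, reasons
    span = t[-1] - t[0]
    if span < 120.0:
        for k in names:
            reasons[k] = "recording shorter than 2 min"
        return vals, reasons
    d = np.diff(nn)
    vals["mean_nn"] = float(np.mean(nn))
    vals["median_nn"] = float(np.median(nn))
    vals["min_nn"] = float(np.min(nn))
    vals["max_nn"] = float(np.max(nn))
    vals["range_nn"] = vals["max_nn"] - vals["min_nn"]
    vals["sdnn"] = float(np.std(nn, ddof=1))
    vals["rmssd"] = float(np.sqrt(np.mean(d ** 2))) if d.size else np.nan
    vals["sdsd"] = float(np.std(d, ddof=1)) if d.size > 1 else np.nan
    vals["cvnn"] = vals["sdnn"] / vals["mean_nn"]
    vals["cvsd"] = vals["rmssd"] / vals["mean_nn"]
    vals["pnn50"] = float(100.0 * np.mean(np.abs(d) > 50.0)) if d.size else np.nan
    vals["pnn20"] = float(100.0 * np.mean(np.abs(d) > 20.0)) if d.size else np.nan
    for p in (5, 25, 75, 95):
        vals[f"prc{p}_nn"] = float(np.percentile(nn, p))
    vals["iqr_nn"] = vals["prc75_nn"] - vals["prc25_nn"]
    for mins in (1, 2, 5):
        seg_len = 60.0 * mins
        n_seg = int(np.floor(span / seg_len))
        if n_seg < 2:
            reasons[f"sdann_{mins}"] = reasons[f"sdnni_{mins}"] = \
                f"fewer than 2 complete {mins}-min segments"
            continue
        idx = np.clip(((t - t[0]) / seg_len).astype(int), 0, n_seg - 1)
        means = [np.mean(nn[idx == s]) for s in range(n_seg) if np.any(idx == s)]
        sds = [np.std(nn[idx == s], ddof=1) for s in range(n_seg)
               if np.sum(idx == s) > 1]
        vals[f"sdann_{mins}"] = float(np.std(means, ddof=1)) if len(means) > 1 else np.nan
        vals[f"sdnni_{mins}"] = float(np.mean(sds)) if sds else np.nan
    hist, _ = np.histogram(nn, bins=np.arange(
        np.floor(nn.min() / HTI_BIN_MS) * HTI_BIN_MS,
        nn.max() + HTI_BIN_MS, HTI_BIN_MS))
    mode_count = hist.max() if hist.size else 0
    if mode_count > 0:
        vals["hti"] = float(nn.size / mode_count)
        vals["tinn"] = _tinn(nn)
    else:
        reasons["hti"] = reasons["tinn"] = "degenerate histogram"
    return vals, reasons


# --------------------------------------------------------------------------
# frequency domain
# --------------------------------------------------------------------------

def _ls_psd(t: np.ndarray, nn: np.ndarray,
            fmax: float = 0.4, nfreq: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Lomb-Scargle PSD (ms^2/Hz) of the unevenly-sampled NN series.

    Scaled so that the integral over frequency approximates the series
    variance (Parseval-style normalisation for a quasi-uniform beat grid).
    """
    span = t[-1] - t[0]
    f = np.linspace(max(1.0 / span, 1e-4), fmax, nfreq)
    y = nn - np.mean(nn)
    pg = lombscargle(t, y, 2 * np.pi * f)
    psd = pg * 2.0 * span / t.size
    return f, psd


def _band_power(f: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    m = (f >= band[0]) & (f < band[1])
    if not np.any(m):
        return 0.0
    return float(np.trapezoid(psd[m], f[m]))


def compute_frequency_domain(rr: RRSeries) -> tuple[dict, dict]:
    """The 6 spectral metrics from a Lomb-Scargle periodogram."""
    t, nn = _nn(rr)
    names = [k for k, s in METRIC_REGISTRY.items() if s.domain == "frequency"]
    vals = {k: np.nan for k in names}
    reasons: dict = {}
    if nn.size < 10 or t[-1] - t[0] < 300.0:
        for k in names:
            reasons[k] = "need at least 5 min of beats"
        return vals, reasons
    f, psd = _ls_psd(t, nn)
    lf = _band_power(f, psd, LF_BAND)
    hf = _band_power(f, psd, HF_BAND)
    tp = _band_power(f, psd, (TP_BAND[0], TP_BAND[1]))
    vals["lf_power"], vals["hf_power"], vals["total_power"] = lf, hf, tp
    if hf > 0:
        vals["lf_hf_ratio"] = lf / hf
    else:
        reasons["lf_hf_ratio"] = "zero HF power"
    if lf + hf > 0:
        vals["lfnu"] = 100.0 * lf / (lf + hf)
        vals["hfnu"] = 100.0 * hf / (lf + hf)
    else:
        reasons["lfnu"] = reasons["hfnu"] = "LF + HF power is zero"
    return vals, reasons


# --------------------------------------------------------------------------
# complexity / information domain
# --------------------------------------------------------------------------

def _apen(x: np.ndarray, m: int, r: float) -> float:
    """Approximate entropy (self-matches included, phi^m - phi^{m+1})."""
    def phi(mm: int) -> float:
        tmpl = np.lib.stride_tricks.sliding_window_view(x, mm)
        n = tmpl.shape[0]
        cnt = np.zeros(n)
        for k in range(mm):
            col = tmpl[:, k]
            if k == 0:
                dm = np.abs(col[:, None] - col[None, :])
            else:
                np.maximum(dm, np.abs(col[:, None] - col[None, :]), out=dm)
        cnt = np.mean(dm <= r, axis=1)
        return float(np.mean(np.log(cnt)))
    return phi(m) - phi(m + 1)


def _fuzzy_entropy(x: np.ndarray, m: int, r: float) -> float:
    """Fuzzy entropy: baseline-removed templates, exp(-(d/r)^2) membership."""
    def phi(mm: int) -> float:
        tmpl = np.lib.stride_tricks.sliding_window_view(x, mm)
        tmpl = tmpl - tmpl.mean(axis=1, keepdims=True)
        n = tmpl.shape[0]
        for k in range(mm):
            col = tmpl[:, k]
            if k == 0:
                dm = np.abs(col[:, None] - col[None, :])
            else:
                np.maximum(dm, np.abs(col[:, None] - col[None, :]), out=dm)
        sim = np.exp(-((dm / r) ** 2))
        np.fill_diagonal(sim, 0.0)
        return float(np.sum(sim) / (n * (n - 1)))
    return float(np.log(phi(m)) - np.log(phi(m + 1)))


def _perm_entropy(x: np.ndarray, order: int) -> float:
    """Permutation entropy, normalized by ln(order!)."""
    import math
    tmpl = np.lib.stride_tricks.sliding_window_view(x, order)
    ranks = np.argsort(np.argsort(tmpl, axis=1), axis=1)
    codes = ranks @ (order ** np.arange(order))
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = -np.sum(p * np.log(p))
    return float(h / math.log(math.factorial(order)))


def _hist_probs(x: np.ndarray) -> np.ndarray:
    nbins = max(8, int(np.ceil(np.sqrt(x.size))))
    hist, _ = np.histogram(x, bins=nbins)
    p = hist / hist.sum()
    return p[p > 0]


def _dfa(x: np.ndarray, scales: np.ndarray) -> float:
    """Detrended fluctuation analysis exponent over the given scales."""
    y = np.cumsum(x - np.mean(x))
    flucts = []
    used = []
    for s in scales:
        s = int(s)
        n_seg = y.size // s
        if n_seg < 2:
            continue
        segs = y[: n_seg * s].reshape(n_seg, s)
        tt = np.arange(s)
        # linear detrend per segment
        tm = tt - tt.mean()
        beta = (segs @ tm) / np.sum(tm ** 2)
        resid = segs - segs.mean(axis=1, keepdims=True) - beta[:, None] * tm
        flucts.append(np.sqrt(np.mean(resid ** 2)))
        used.append(s)
    if len(used) < 3:
        raise ValueError("too few usable scales for DFA")
    coef = np.polyfit(np.log(used), np.log(flucts), 1)
    return float(coef[0])


def _mfdfa_h(x: np.ndarray, qs: np.ndarray,
             scales: Optional[np.ndarray] = None) -> dict[float, float]:
    """Generalized Hurst exponents h(q) via multifractal DFA."""
    y = np.cumsum(x - np.mean(x))
    n = y.size
    if scales is None:
        scales = np.unique(np.floor(np.geomspace(8, max(n // 4, 9), 10)).astype(int))
    f2 = []
    used = []
    for s in scales:
        n_seg = n // s
        if n_seg < 4:
            continue
        segs = y[: n_seg * s].reshape(n_seg, s)
        tt = np.arange(s)
        tm = tt - tt.mean()
        beta = (segs @ tm) / np.sum(tm ** 2)
        resid = segs - segs.mean(axis=1, keepdims=True) - beta[:, None] * tm
        f2.append(np.mean(resid ** 2, axis=1))
        used.append(s)
    if len(used) < 3:
        raise ValueError("too few usable scales for MFDFA")
    out = {}
    logs = np.log(used)
    for q in qs:
        if abs(q) < 1e-12:
            fq = [np.exp(0.5 * np.mean(np.log(f2s + 1e-300))) for f2s in f2]
        else:
            fq = [(np.mean((f2s + 1e-300) ** (q / 2.0))) ** (1.0 / q) for f2s in f2]
        out[float(q)] = float(np.polyfit(logs, np.log(fq), 1)[0])
    return out


def _higuchi(x: np.ndarray, kmax: int) -> float:
    n = x.size
    lks = []
    ks = []
    for k in range(1, kmax + 1):
        lk = 0.0
        cnt = 0
        for m0 in range(k):
            idx = np.arange(m0, n, k)
            if idx.size < 2:
                continue
            length = np.sum(np.abs(np.diff(x[idx]))) * (n - 1) / (
                (idx.size - 1) * k)
            lk += length / k
            cnt += 1
        if cnt:
            lks.append(lk / cnt)
            ks.append(k)
    coef = np.polyfit(np.log(1.0 / np.asarray(ks)), np.log(lks), 1)
    return float(coef[0])


def _katz(x: np.ndarray) -> float:
    d1 = np.diff(x)
    L = float(np.sum(np.sqrt(1.0 + d1 ** 2)))
    d = float(np.max(np.sqrt(np.arange(1, x.size) ** 2 + (x[1:] - x[0]) ** 2)))
    n = x.size - 1
    return float(np.log10(n) / (np.log10(n) + np.log10(d / L)))


def _petrosian(x: np.ndarray) -> float:
    d = np.diff(x)
    n_delta = int(np.sum(d[1:] * d[:-1] < 0))
    n = x.size
    return float(np.log10(n) / (np.log10(n)
                                + np.log10(n / (n + 0.4 * n_delta))))


def _lz76(symbols: np.ndarray) -> int:
    """Lempel-Ziv 1976 production complexity (Kaspar-Schuster scan)."""
    s = symbols.tolist()
    n = len(s)
    i, c = 0, 1
    u, v, vmax = 1, 1, 1
    while u + v <= n:
        if s[i + v - 1] == s[u + v - 1]:
            v += 1
        else:
            vmax = max(v, vmax)
            i += 1
            if i == u:  # no prior reproduction long enough: new component
                c += 1
                u += vmax
                v, i, vmax = 1, 0, 1
            else:
                v = 1
    if v != 1:
        c += 1
    return c


def _lzc(x: np.ndarray, nbins: int = 2) -> float:
    """Normalized Lempel-Ziv complexity; 2 bins = median split."""
    qs = np.quantile(x, np.linspace(0, 1, nbins + 1)[1:-1])
    sym = np.digitize(x, qs)
    c = _lz76(sym)
    n = x.size
    return float(c * np.log(n) / np.log(nbins) / n)


def _hurst_rs(x: np.ndarray) -> float:
    """Rescaled-range Hurst exponent."""
    n = x.size
    sizes = np.unique(np.floor(np.geomspace(10, n // 2, 8)).astype(int))
    rs = []
    used = []
    for s in sizes:
        n_seg = n // s
        if n_seg < 1:
            continue
        vals = []
        for v in range(n_seg):
            seg = x[v * s:(v + 1) * s]
            z = np.cumsum(seg - seg.mean())
            r = z.max() - z.min()
            sd = seg.std(ddof=1)
            if sd > 0:
                vals.append(r / sd)
        if vals:
            rs.append(np.mean(vals))
            used.append(s)
    if len(used) < 3:
        raise ValueError("series too short for R/S analysis")
    return float(np.polyfit(np.log(used), np.log(rs), 1)[0])


def _corr_dim(x: np.ndarray, emb: int, n_radii: int = 8) -> float:
    """Grassberger-Procaccia correlation dimension."""
    tmpl = np.lib.stride_tricks.sliding_window_view(x, emb)
    if tmpl.shape[0] > 1200:  # subsample pairs for tractability
        step = tmpl.shape[0] // 1200 + 1
        tmpl = tmpl[::step]
    from scipy.spatial.distance import pdist
    d = pdist(tmpl)
    d = d[d > 0]
    if d.size < 100:
        raise ValueError("too few distinct pairs for correlation dimension")
    radii = np.exp(np.linspace(np.log(np.quantile(d, 0.02)),
                               np.log(np.quantile(d, 0.5)), n_radii))
    c = np.array([np.mean(d < r) for r in radii])
    ok = c > 0
    if ok.sum() < 3:
        raise ValueError("degenerate correlation sum")
    return float(np.polyfit(np.log(radii[ok]), np.log(c[ok]), 1)[0])


def _coarse_grain(x: np.ndarray, scale: int) -> np.ndarray:
    n = (x.size // scale) * scale
    return x[:n].reshape(-1, scale).mean(axis=1)


def compute_complexity_domain(rr: RRSeries,
                              hr: Optional[UniformHRSeries] = None
                              ) -> tuple[dict, dict]:
    """The 54 nonlinear / information-theoretic metrics."""
    _, nn = _nn(rr)
    names = [k for k, s in METRIC_REGISTRY.items() if s.domain == "complexity"]
    vals = {k: np.nan for k in names}
    reasons: dict = {}

    def attempt(name: str, fn: Callable[[], float]) -> None:
        try:
            vals[name] = float(fn())
        except Exception as exc:  # per-metric isolation, never abort
            reasons[name] = str(exc)

    if nn.size < 10:
        for k in names:
            reasons[k] = "too few NN intervals"
        return vals, reasons
    d = np.diff(nn)
    var_d = np.var(d, ddof=1) if d.size > 1 else 0.0
    var_nn = np.var(nn, ddof=1)
    sd1 = np.sqrt(var_d / 2.0)
    sd2_sq = 2.0 * var_nn - var_d / 2.0
    sd2 = np.sqrt(max(sd2_sq, 0.0))
    vals["sd1"], vals["sd2"] = float(sd1), float(sd2)
    if sd2 > 0:
        vals["sd1_sd2_ratio"] = float(sd1 / sd2)
    vals["ellipse_area"] = float(np.pi * sd1 * sd2)
    if sd1 > 0:
        vals["csi"] = float(sd2 / sd1)
        vals["csi_modified"] = float(sd2 ** 2 / sd1)
    else:
        reasons["csi"] = reasons["csi_modified"] = "zero SD1"
    if sd1 * sd2 > 0:
        vals["cvi"] = float(np.log10(16.0 * sd1 * sd2))
    else:
        reasons["cvi"] = "degenerate Poincare ellipse"

    sd = np.std(nn)
    if sd == 0:
        for k in ("apen", "apen_m3", "sampen", "sampen_m3", "fuzzy_entropy",
                  "fuzzy_entropy_m3"):
            reasons[k] = "zero variance"
    else:
        r = 0.2 * sd
        attempt("apen", lambda: _apen(nn, 2, r))
        attempt("apen_m3", lambda: _apen(nn, 3, r))
        for name, m in (("sampen", 2), ("sampen_m3", 3)):
            est = entropy_core.sample_entropy(nn, m=m, r=0.2)
            if est.defined:
                vals[name] = est.value
            else:
                reasons[name] = est.reason
        attempt("fuzzy_entropy", lambda: _fuzzy_entropy(nn, 2, r))
        attempt("fuzzy_entropy_m3", lambda: _fuzzy_entropy(nn, 3, r))
        for s in range(1, 11):
            cg = _coarse_grain(nn, s)
            if cg.size < 30:
                reasons[f"mse_{s}"] = "coarse-grained series too short"
                continue
            est = entropy_core.sample_entropy(cg, m=2, r=r, r_is_relative=False)
            if est.defined:
                vals[f"mse_{s}"] = est.value
            else:
                reasons[f"mse_{s}"] = est.reason
        mse_vals = np.array([vals[f"mse_{s}"] for s in range(1, 11)])
        ok = np.isfinite(mse_vals)
        if ok.sum() >= 3:
            vals["mse_area"] = float(np.sum(mse_vals[ok]))
            vals["mse_slope"] = float(np.polyfit(
                np.arange(1, 11)[ok], mse_vals[ok], 1)[0])
        else:
            reasons["mse_area"] = reasons["mse_slope"] = "too few MSE scales"

    p = _hist_probs(nn)
    vals["shannon_entropy"] = float(-np.sum(p * np.log(p)))
    vals["renyi_entropy_2"] = float(-np.log(np.sum(p ** 2)))
    attempt("perm_entropy_3", lambda: _perm_entropy(nn, 3))
    attempt("perm_entropy_4", lambda: _perm_entropy(nn, 4))

    if hr is not None:
        est = entropy_core.entropy_rate(hr)
        if est.defined:
            vals["entropy_rate"] = est.value
        else:
            reasons["entropy_rate"] = est.reason
    else:
        reasons["entropy_rate"] = "no uniform HR series supplied"

    attempt("dfa_alpha1", lambda: _dfa(nn, np.arange(4, 17)))
    attempt("dfa_alpha2", lambda: _dfa(nn, np.unique(
        np.floor(np.geomspace(16, 64, 8)).astype(int))))
    attempt("dfa_alpha_full", lambda: _dfa(nn, np.unique(
        np.floor(np.geomspace(4, 64, 12)).astype(int))))

    try:
        hq = _mfdfa_h(nn, np.arange(-5, 6))
        for q in range(-5, 6):
            tag = f"qm{-q}" if q < 0 else f"qp{q}"
            vals[f"mfdfa_h_{tag}"] = hq[float(q)]
        vals["mfdfa_width"] = hq[-5.0] - hq[5.0]
    except Exception as exc:
        for q in range(-5, 6):
            tag = f"qm{-q}" if q < 0 else f"qp{q}"
            reasons[f"mfdfa_h_{tag}"] = str(exc)
        reasons["mfdfa_width"] = str(exc)

    attempt("correlation_dim", lambda: _corr_dim(nn, 2))
    attempt("correlation_dim_emb3", lambda: _corr_dim(nn, 3))
    attempt("higuchi_fd", lambda: _higuchi(nn, 10))
    attempt("higuchi_fd_kmax20", lambda: _higuchi(nn, 20))
    attempt("katz_fd", lambda: _katz(nn))
    attempt("petrosian_fd", lambda: _petrosian(nn))
    attempt("lzc", lambda: _lzc(nn, 2))
    attempt("lzc_3bin", lambda: _lzc(nn, 3))
    attempt("hurst_rs", lambda: _hurst_rs(nn))
    return vals, reasons


# --------------------------------------------------------------------------
# specialized domain
# --------------------------------------------------------------------------

def _find_ectopics(rr: RRSeries) -> np.ndarray:
    """Indices of flagged beats with a short-then-compensatory pattern."""
    idx = []
    for i in np.flatnonzero(rr.artifact_flags):
        if 2 <= i < rr.rr.size - 16:
            if (rr.rr[i] < 0.8 * rr.rr[i - 1]
                    and rr.rr[i + 1] > 1.1 * rr.rr[i - 1]):
                idx.append(i)
    return np.asarray(idx, dtype=int)


def compute_specialized(rr: RRSeries) -> tuple[dict, dict]:
    """The 9 specialized metrics (HRT, variability and spectral shape)."""
    t, nn = _nn(rr)
    names = [k for k, s in METRIC_REGISTRY.items() if s.domain == "specialized"]
    vals = {k: np.nan for k in names}
    reasons: dict = {}
    if nn.size < 10:
        for k in names:
            reasons[k] = "too few NN intervals"
        return vals, reasons
    mean_nn = float(np.mean(nn))
    vals["cv_percent"] = float(100.0 * np.std(nn, ddof=1) / mean_nn)
    med = float(np.median(nn))
    mad = float(np.median(np.abs(nn - med)))
    vals["madnn"] = mad
    vals["mcvnn"] = mad / med if med > 0 else np.nan
    slope = np.polyfit(t / 60.0, nn, 1)[0]
    vals["trend_slope"] = float(slope)

    if t[-1] - t[0] >= 300.0:
        f, psd = _ls_psd(t, nn)
        total = np.trapezoid(psd, f)
        if total > 0:
            cf = float(np.trapezoid(f * psd, f) / total)
            vals["centroid_freq"] = cf
            vals["freq_bandwidth"] = float(np.sqrt(
                np.trapezoid((f - cf) ** 2 * psd, f) / total))
            pn = psd / np.sum(psd)
            pn = pn[pn > 0]
            vals["spectral_entropy"] = float(-np.sum(pn * np.log(pn))
                                             / np.log(psd.size))
        else:
            for k in ("centroid_freq", "freq_bandwidth", "spectral_entropy"):
                reasons[k] = "zero spectral power"
    else:
        for k in ("centroid_freq", "freq_bandwidth", "spectral_entropy"):
            reasons[k] = "need at least 5 min of beats"

    ect = _find_ectopics(rr)
    if ect.size == 0:
        reasons["hrt_onset"] = reasons["hrt_slope"] = \
            "no annotated ectopic beats with compensatory pause"
    else:
        onsets = []
        slopes = []
        for i in ect:
            pre = rr.rr[i - 2:i]
            post = rr.rr[i + 2:i + 4]
            if pre.size == 2 and post.size == 2 and pre.sum() > 0:
                onsets.append(100.0 * (post.sum() - pre.sum()) / pre.sum())
            tach = rr.rr[i + 2:i + 17]
            if tach.size >= 5:
                best = -np.inf
                for j in range(tach.size - 4):
                    b = np.polyfit(np.arange(5), tach[j:j + 5], 1)[0]
                    best = max(best, b)
                slopes.append(best)
        if onsets:
            vals["hrt_onset"] = float(np.mean(onsets))
        else:
            reasons["hrt_onset"] = "no evaluable ectopic context"
        if slopes:
            vals["hrt_slope"] = float(np.mean(slopes))
        else:
            reasons["hrt_slope"] = "no evaluable post-ectopic run"
    return vals, reasons


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------

def compute_all(rr: RRSeries, hr: Optional[UniformHRSeries] = None,
                subject: str = "", visit: str = "",
                position: str = "") -> MetricVector:
    """All 94 metrics for one window; per-metric failures stay isolated."""
    vals: dict = {}
    reasons: dict = {}
    for fn in (compute_time_domain, compute_frequency_domain,
               compute_specialized):
        v, re = fn(rr)
        vals.update(v)
        reasons.update(re)
    v, re = compute_complexity_domain(rr, hr)
    vals.update(v)
    reasons.update(re)
    return MetricVector(subject or rr.subject, visit or rr.visit, position,
                        vals, reasons)


def battery_matrix(vectors: list[MetricVector]) -> pd.DataFrame:
    """Wide matrix: one row per subject-visit-position, 94 metric columns."""
    rows = []
    for v in vectors:
        row = {"subject": v.subject, "visit": v.visit, "position": v.position}
        row.update(v.values)
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject", "visit", "position",
                                       *METRIC_REGISTRY])


def flag_outliers(matrix: pd.DataFrame, k_iqr: float = 5.0) -> pd.DataFrame:
    """Flag (never remove) values beyond k_iqr IQRs from the column median."""
    flags = pd.DataFrame(False, index=matrix.index,
                         columns=[c for c in matrix.columns
                                  if c in METRIC_REGISTRY])
    for c in flags.columns:
        col = matrix[c]
        q1, q3 = col.quantile([0.25, 0.75])
        iqr = q3 - q1
        if not np.isfinite(iqr) or iqr == 0:
            continue
        med = col.median()
        flags[c] = (col - med).abs() > k_iqr * iqr
    return flags
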