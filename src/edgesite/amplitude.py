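"""Amplitude-distribution analysis of the band-passed signal.

Edge and center site groups are compared through

* probability density functions of the subsampled amplitudes,
* total signal power (RMS of the pooled amplitudes) with a Brown-Forsythe
  equal-variance test,
* a binomial threshold scan over the cumulative P(a < x) (negative range)
  and reverse-cumulative P(a > x) (positive range) distributions, and
* edge/center PDF-ratio summaries over the negative amplitude range.

The scan's null hypothesis at each threshold x is that each beyond-threshold
sample is an edge sample with probability p_e = N_e / (N_e + N_c), where
N_e and N_c are the groups' total retained sample counts; the observed
beyond-threshold edge count is tested one-sidedly against
Binomial(k_e + k_c, p_e), and symmetrically for the center direction with
p_c.  With 100 thresholds per side and two directions the per-test level is
Bonferroni-corrected for 200 comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import AmplitudePool

__all__ = [
    "AmplitudePDF",
    "ScanResult",
    "PowerComparison",
    "PDFRatioSummary",
    "pdf",
    "rms",
    "cumulative_scan",
    "pct_beyond",
    "brown_forsythe",
    "pdf_ratio_summary",
    "binom_sf",
]

PLOT_FLOOR = 1e-9  # probabilities below this are masked in displays only


@dataclass
class AmplitudePDF:
    """Histogram-based amplitude probability distribution."""

    bin_edges_uV: np.ndarray
    probability: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if abs(float(self.probability.sum()) - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")
        if np.any(self.counts < 0):
            raise ValueError("negative bin count")

    @property
    def bin_centers_uV(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_uV[:-1] + self.bin_edges_uV[1:])

    def masked_probability(self, floor: float = PLOT_FLOOR) -> np.ndarray:
        """Display copy with probabilities below ``floor`` set to NaN."""
        p = self.probability.astype(float).copy()
        p[p < floor] = np.nan
        return p


@dataclass
class ScanResult:
    """Per-threshold counts, p-values and significance of one scan side."""

    side: str  # "negative" | "positive"
    thresholds_uV: np.ndarray
    k_edge: np.ndarray
    k_center: np.ndarray
    p_edge_direction: np.ndarray
    p_center_direction: np.ndarray
    p_e: float
    p_c: float
    alpha_corrected: float
    sig_edge: np.ndarray
    sig_center: np.ndarray
    threshold_edge_uV: float | None
    pct_edge: float | None
    pct_center: float | None
    n_edge: int = 0
    n_center: int = 0

    @property
    def n_comparisons(self) -> int:
        """Bonferroni denominator implied by the corrected level."""
        # alpha_corrected = alpha / (2 * n_steps); both directions counted
        return 2 * len(self.thresholds_uV)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold_uV": self.thresholds_uV,
                "k_edge": self.k_edge,
                "k_center": self.k_center,
                "p_edge_direction": self.p_edge_direction,
                "p_center_direction": self.p_center_direction,
                "sig_edge": self.sig_edge,
                "sig_center": self.sig_center,
            }
        )


@dataclass
class PowerComparison:
    """RMS power of two groups with a Brown-Forsythe equal-variance test."""

    rms_edge_uV: float
    rms_center_uV: float
    brown_forsythe_F: float
    p_value: float
    n_edge: int
    n_center: int


@dataclass
class PDFRatioSummary:
    """Edge-to-center PDF ratio over the negative amplitude range."""

    bin_centers_uV: np.ndarray
    ratio: np.ndarray  # NaN where both probabilities are zero
    tail_sum_ratio: float  # sum(p_edge)/sum(p_center) below the tail cut
    tail_cut_uV: float
    mean_ratio: float  # mean of finite per-bin ratios over the range
    n_infinite: int = 0


def _samples(pool: AmplitudePool | np.ndarray) -> np.ndarray:
    if isinstance(pool, AmplitudePool):
        return np.asarray(pool.samples_uV, dtype=float)
    return np.asarray(pool, dtype=float)


def pdf(pool: AmplitudePool | np.ndarray, bin_width_uV: float = 1.0,
        limit_uV: float = 1000.0) -> AmplitudePDF:
    """Amplitude PDF on uniform bins spanning [-limit, +limit]."""
    x = _samples(pool)
    if x.size == 0:
        raise ValueError("empty amplitude pool")
    n_bins = int(round(2 * limit_uV / bin_width_uV))
    edges = -limit_uV + bin_width_uV * np.arange(n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)  # last bin closed at +limit
    prob = counts / x.size
    return AmplitudePDF(edges, prob, counts)


def rms(pools: AmplitudePool | np.ndarray | Iterable) -> float:
    """Root-mean-square amplitude over one pool or pooled over several."""
    if isinstance(pools, (AmplitudePool, np.ndarray)):
        parts = [_samples(pools)]
    else:
        parts = [_samples(p) for p in pools]
    x = np.concatenate(parts) if len(parts) > 1 else parts[0]
    if x.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean(np.square(x))))


def binom_sf(k: np.ndarray | int, n: np.ndarray | int,
             p: float) -> np.ndarray:
    """P(K >= k) for K ~ Binomial(n, p), exact via the incomplete beta."""
    k = np.asarray(k)
    n = np.asarray(n)
    # sf(k-1) = P(K >= k); scipy evaluates this through bdtrc (regularized
    # incomplete beta), numerically exact at large n
    return stats.binom.sf(k - 1, n, p)


def _beyond_counts(sorted_samples: np.ndarray, thresholds: np.ndarray,
                   side: str) -> np.ndarray:
    if side == "negative":  # strict a < x
        return np.searchsorted(sorted_samples, thresholds, side="left")
    # strict a > x
    return sorted_samples.size - np.searchsorted(
        sorted_samples, thresholds, side="right")


def scan_thresholds(side: str, n_steps: int = 100,
                    limit_uV: float = 1000.0,
                    start_uV: float = 0.0) -> np.ndarray:
    """Uniform threshold grid over (start, +-limit] for one scan side."""
    steps = start_uV + (limit_uV - start_uV) * np.arange(
        1, n_steps + 1) / n_steps
    if side == "negative":
        return -steps
    if side == "positive":
        return steps
    raise ValueError("side must be 'negative' or 'positive'")


def cumulative_scan(
    edge: AmplitudePool | np.ndarray,
    center: AmplitudePool | np.ndarray,
    side: str,
    n_steps: int = 100,
    alpha: float = 0.05,
    limit_uV: float = 1000.0,
    thresholds_uV: np.ndarray | None = None,
    n_sides: int = 2,
) -> ScanResult:
    """Binomial threshold scan of cumulative amplitude distributions.

    At each threshold x the number of edge samples beyond x (``a < x`` on
    the negative side, ``a > x`` on the positive side) is tested against
    the binomial null with success probability ``p_e``; the reverse test
    uses the center count and ``p_c``.  Significance is assessed at
    ``alpha / (n_sides * n_steps)`` — with the default two sides this is
    the Bonferroni correction for 200 comparisons.

    The selected ``threshold_edge_uV`` is the least extreme threshold whose
    edge-direction test is significant (the maximal amplitude for edge
    significance on the negative side, the minimal on the positive side),
    and ``pct_edge``/``pct_center`` give the percentage of each group's
    same-sign samples beyond it.
    """
    e = np.sort(_samples(edge))
    c = np.sort(_samples(center))
    if e.size == 0 or c.size == 0:
        raise ValueError("both pools must be nonempty")
    if thresholds_uV is None:
        thresholds_uV = scan_thresholds(side, n_steps, limit_uV)
    else:
        thresholds_uV = np.asarray(thresholds_uV, dtype=float)
        n_steps = thresholds_uV.size
    n_e, n_c = e.size, c.size
    p_e = n_e / (n_e + n_c)
    p_c = n_c / (n_e + n_c)
    k_e = _beyond_counts(e, thresholds_uV, side)
    k_c = _beyond_counts(c, thresholds_uV, side)
    n_beyond = k_e + k_c
    p_edge_dir = np.where(n_beyond > 0, binom_sf(k_e, n_beyond, p_e), 1.0)
    p_center_dir = np.where(n_beyond > 0, binom_sf(k_c, n_beyond, p_c), 1.0)
    alpha_corr = alpha / (n_sides * n_steps)
    sig_e = p_edge_dir < alpha_corr
    sig_c = p_center_dir < alpha_corr

    threshold_sel: float | None = None
    pct_e: float | None = None
    pct_c: float | None = None
    if sig_e.any():
        idx = int(np.flatnonzero(sig_e)[0])  # grids run least -> most extreme
        threshold_sel = float(thresholds_uV[idx])
        pct_e = pct_beyond(e, threshold_sel, side)
        pct_c = pct_beyond(c, threshold_sel, side)
    return ScanResult(
        side=side,
        thresholds_uV=thresholds_uV,
        k_edge=k_e,
        k_center=k_c,
        p_edge_direction=p_edge_dir,
        p_center_direction=p_center_dir,
        p_e=p_e,
        p_c=p_c,
        alpha_corrected=alpha_corr,
        sig_edge=sig_e,
        sig_center=sig_c,
        threshold_edge_uV=threshold_sel,
        pct_edge=pct_e,
        pct_center=pct_c,
        n_edge=n_e,
        n_center=n_c,
    )


def pct_beyond(pool: AmplitudePool | np.ndarray, threshold_uV: float,
               side: str) -> float:
    """Percentage of a group's same-sign samples beyond a threshold.

    On the negative side: 100 x #(a < x) / #(a < 0); positive side uses
    strict ``a > x`` over the positive samples.
    """
    x = _samples(pool)
    if side == "negative":
        signed = x[x < 0]
        beyond = np.sum(signed < threshold_uV)
    elif side == "positive":
        signed = x[x > 0]
        beyond = np.sum(signed > threshold_uV)
    else:
        raise ValueError("side must be 'negative' or 'positive'")
    if signed.size == 0:
        raise ValueError(f"no {side} samples in pool")
    return 100.0 * float(beyond) / signed.size


def brown_forsythe(edge: AmplitudePool | np.ndarray,
                   center: AmplitudePool | np.ndarray) -> PowerComparison:
    """Brown-Forsythe (median-centered Levene) test of equal signal power."""
    e = _samples(edge)
    c = _samples(center)
    if e.size < 2 or c.size < 2:
        raise ValueError("both pools must have at least 2 samples")
    stat, p = stats.levene(e, c, center="median")
    return PowerComparison(
        rms_edge_uV=rms(e),
        rms_center_uV=rms(c),
        brown_forsythe_F=float(stat),
        p_value=float(p),
        n_edge=int(e.size),
        n_center=int(c.size),
    )


def pdf_ratio_summary(pdf_edge: AmplitudePDF, pdf_center: AmplitudePDF,
                      tail_cut_uV: float = -350.0) -> PDFRatioSummary:
    """Edge-to-center probability ratio over the negative range (0 to -1000).

    Bins where both probabilities are zero are skipped (NaN); bins with a
    zero center probability but nonzero edge probability are flagged
    infinite and excluded from the mean.  The ``tail_sum_ratio`` aggregates
    all probability mass below ``tail_cut_uV`` into a single ratio.
    """
    if not np.array_equal(pdf_edge.bin_edges_uV, pdf_center.bin_edges_uV):
        raise ValueError("PDFs must share identical bins")
    centers = pdf_edge.bin_centers_uV
    neg = centers < 0
    pe = pdf_edge.probability[neg]
    pc = pdf_center.probability[neg]
    ratio = np.full(pe.shape, np.nan)
    both_zero = (pe == 0) & (pc == 0)
    inf_mask = (pc == 0) & (pe > 0)
    ok = ~both_zero & ~inf_mask
    ratio[ok] = pe[ok] / pc[ok]
    ratio[inf_mask] = np.inf
    tail = centers[neg] < tail_cut_uV
    pc_tail = pc[tail].sum()
    tail_ratio = float(pe[tail].sum() / pc_tail) if pc_tail > 0 else np.nan
    finite = np.isfinite(ratio)
    mean_ratio = float(np.mean(ratio[finite])) if finite.any() else np.nan
    return PDFRatioSummary(
        bin_centers_uV=centers[neg],
        ratio=ratio,
        tail_sum_ratio=tail_ratio,
        tail_cut_uV=tail_cut_uV,
        mean_ratio=mean_ratio,
        n_infinite=int(inf_mask.sum()),
    )
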