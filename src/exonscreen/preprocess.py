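"""Probe-level preprocessing for exon arrays.

The chain mirrors the standard RMA-style workflow for Affymetrix exon
arrays: convolution background correction, optional GC-bin adjustment,
quantile normalization across arrays, probeset summarization (mean of
log2 probe intensities) and low-expression filtering at the gene and
exon-probeset level.  Stages are pure functions over :class:`ProbeMatrix`
and :class:`SummaryMatrix`; the intended order is

    background_correct -> gc_adjust -> quantile_normalize ->
    summarize_probesets -> filter_low_expression
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger("exonscreen")

GENE = "gene"
EXON = "exon"

#: strictly positive floor for corrected intensities
_POSITIVE_FLOOR = 2.0 ** -20


@dataclass
class ProbeMatrix:
    """Linear-scale probe intensities plus annotation maps.

    Parameters
    ----------
    values
        DataFrame of non-negative linear intensities, rows indexed by
        probe id, columns by sample id.
    probe_to_probeset
        Series mapping each probe id to exactly one probeset id.
    probeset_to_feature
        DataFrame indexed by probeset id with columns ``feature_id``
        (the parent transcript), ``kind`` (``"gene"`` or ``"exon"``)
        and ``exon_index`` (integer for exon probesets, ``-1`` for
        gene probesets).
    probe_gc
        Optional Series of per-probe GC fraction in [0, 1].
    """

    values: pd.DataFrame
    probe_to_probeset: pd.Series
    probeset_to_feature: pd.DataFrame
    probe_gc: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("probe intensities must be non-negative")
        missing = self.values.index.difference(self.probe_to_probeset.index)
        if len(missing):
            raise ValueError(f"{len(missing)} probes lack a probeset mapping")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class SummaryMatrix:
    """Log2-scale summarized values, one row per feature (probeset).

    ``meta`` is indexed like ``values`` and carries ``kind``
    (gene/exon), ``feature_id`` (parent transcript) and ``exon_index``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.values).all():
            raise ValueError("summary values must be finite")
        if self.values.index.has_duplicates:
            raise ValueError("feature ids must be unique")

    def subset(self, kind: str) -> "SummaryMatrix":
        keep = self.meta.index[self.meta["kind"] == kind]
        return SummaryMatrix(self.values.loc[keep], self.meta.loc[keep])


# ---------------------------------------------------------------------------
# background correction
# ---------------------------------------------------------------------------

def estimate_background_params(x: np.ndarray) -> tuple[float, float, float]:
    """Mode-based estimate of (bg_mean, bg_sd, signal_rate) for one array.

    The mode of the intensity distribution is taken as the background
    mean; the spread of the sub-mode values gives the background sd and
    the mean excess of the supra-mode values gives the exponential
    signal rate (1/mean).
    """
    x = np.asarray(x, dtype=float)
    counts, edges = np.histogram(x, bins=128)
    mode = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
    below = x[x < mode]
    above = x[x > mode]
    if below.size < 2 or above.size < 2:
        # degenerate array; fall back to a flat prior
        return float(mode), max(float(np.std(x)), 1e-6), 1.0 / max(float(np.mean(x)), 1e-6)
    bg_sd = float(np.sqrt(np.mean((below - mode) ** 2)))
    signal_mean = float(np.mean(above - mode))
    return float(mode), max(bg_sd, 1e-6), 1.0 / max(signal_mean, 1e-6)


def _rma_posterior_mean(o: np.ndarray, bg_mean: float, bg_sd: float,
                        signal_rate: float) -> np.ndarray:
    """E[signal | observed] under Normal background + Exponential signal."""
    if bg_sd < 1e-8:
        # analytic limit sigma -> 0+: the background is deterministic
        return np.maximum(o - bg_mean, _POSITIVE_FLOOR)
    a = o - bg_mean - bg_sd ** 2 * signal_rate
    za = a / bg_sd
    zb = (o - a) / bg_sd
    num = norm.pdf(za) - norm.pdf(zb)
    den = norm.cdf(za) + norm.cdf(zb) - 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = a + bg_sd * num / den
    # deep-left tail: denominator underflows; posterior mean tends to the
    # exponential prior mean truncated by positivity, which is tiny there
    corrected = np.where(den <= 1e-300, _POSITIVE_FLOOR, corrected)
    return np.maximum(corrected, _POSITIVE_FLOOR)


def background_correct(m: ProbeMatrix, bg_mean: float | None = None,
                       bg_sd: float | None = None,
                       signal_rate: float | None = None) -> ProbeMatrix:
    """RMA convolution background correction, per array.

    Parameters default to per-array mode-based estimates when not
    supplied.  The corrected matrix is strictly positive and the
    correction is monotone non-decreasing in the observed intensity.
    """
    if bg_sd is not None and bg_sd < 0:
        raise ValueError("bg_sd must be non-negative")
    if signal_rate is not None and signal_rate <= 0:
        raise ValueError("signal_rate must be positive")
    out = {}
    for sample in m.values.columns:
        o = m.values[sample].to_numpy(dtype=float)
        if bg_mean is None or bg_sd is None or signal_rate is None:
            e_mean, e_sd, e_rate = estimate_background_params(o)
            mu = bg_mean if bg_mean is not None else e_mean
            sd = bg_sd if bg_sd is not None else e_sd
            rate = signal_rate if signal_rate is not None else e_rate
        else:
            mu, sd, rate = bg_mean, bg_sd, signal_rate
        out[sample] = _rma_posterior_mean(o, mu, sd, rate)
    corrected = pd.DataFrame(out, index=m.values.index)
    return replace(m, values=corrected)


# ---------------------------------------------------------------------------
# GC adjustment
# ---------------------------------------------------------------------------

def gc_adjust(m: ProbeMatrix, n_bins: int = 25) -> ProbeMatrix:
    """Center per-array log2 medians of GC-content bins to the array median.

    A no-op (with a logged notice) when the matrix carries no per-probe
    GC annotation; probes are binned by GC fraction into ``n_bins``
    equal-width bins and each bin's log2 median is shifted to match the
    global per-array median.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if m.probe_gc is None:
        logger.warning("gc_adjust skipped: matrix carries no probe GC annotation")
        return m
    if n_bins == 1:
        return m
    gc = m.probe_gc.reindex(m.values.index).to_numpy(dtype=float)
    bins = np.minimum((gc * n_bins).astype(int), n_bins - 1)
    log_v = np.log2(np.maximum(m.values.to_numpy(dtype=float), _POSITIVE_FLOOR))
    out = log_v.copy()
    for j in range(m.n_samples):
        global_med = np.median(log_v[:, j])
        for b in np.unique(bins):
            sel = bins == b
            out[sel, j] += global_med - np.median(log_v[sel, j])
    adjusted = pd.DataFrame(2.0 ** out, index=m.values.index,
                            columns=m.values.columns)
    return replace(m, values=adjusted)


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(values: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Across-sample quantile normalization (rank-mean algorithm).

    Columns are samples.  After normalization every sample shares the
    identical sorted value vector — the mean, across samples, of the
    per-rank sorted values.  Ties within a sample receive the mean of
    the tied target quantiles.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("quantile normalization needs at least two samples")
    target = np.mean(np.sort(arr, axis=0), axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        # each tie group of equal values occupies a consecutive rank block;
        # it receives the mean of the target quantiles in that block
        _, inverse, counts = np.unique(col, return_inverse=True,
                                       return_counts=True)
        starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
        group_means = np.add.reduceat(target, starts) / counts
        out[:, j] = group_means[inverse]
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def quantile_normalize_probes(m: ProbeMatrix) -> ProbeMatrix:
    """Quantile-normalize the probe intensity matrix across arrays."""
    return replace(m, values=quantile_normalize(m.values))


# ---------------------------------------------------------------------------
# summarization and filtering
# ---------------------------------------------------------------------------

def summarize_probesets(m: ProbeMatrix) -> SummaryMatrix:
    """Summarize probes to probesets as the mean of log2 intensities."""
    log_v = np.log2(np.maximum(m.values.to_numpy(dtype=float), _POSITIVE_FLOOR))
    log_df = pd.DataFrame(log_v, index=m.values.index, columns=m.values.columns)
    probesets = m.probe_to_probeset.reindex(m.values.index)
    summarized = log_df.groupby(probesets).mean()
    meta = m.probeset_to_feature.reindex(summarized.index)
    return SummaryMatrix(summarized, meta)


def filter_low_expression(s: SummaryMatrix, gene_linear_floor: float = 25.0,
                          exon_log2_floor: float = 3.0,
                          aggregate: str = "mean",
                          ) -> tuple[SummaryMatrix, list[str]]:
    """Drop weakly expressed features before statistics.

    Gene-level features are removed when their linear-scale signal,
    aggregated across all arrays, falls below ``gene_linear_floor``
    (default 25); exon probesets are removed when their log2 signal
    aggregated across arrays falls below ``exon_log2_floor`` (default 3).
    ``aggregate`` selects the across-array reduction ("mean", "min" or
    "max").  Returns the retained matrix and the removed feature ids.
    """
    agg_fn = {"mean": np.mean, "min": np.min, "max": np.max}[aggregate]
    kinds = s.meta["kind"]
    log_vals = s.values.to_numpy(dtype=float)
    linear_agg = agg_fn(2.0 ** log_vals, axis=1)
    log_agg = agg_fn(log_vals, axis=1)
    is_gene = (kinds == GENE).to_numpy()
    drop = np.where(is_gene, linear_agg < gene_linear_floor,
                    log_agg < exon_log2_floor)
    removed = list(s.values.index[drop])
    kept = s.values.index[~drop]
    if removed:
        logger.info("filter_low_expression removed %d of %d features",
                    len(removed), len(drop))
    return SummaryMatrix(s.values.loc[kept], s.meta.loc[kept]), removed


def preprocess_pipeline(m: ProbeMatrix, *, gc_bins: int | None = None,
                        bg_params: tuple[float, float, float] | None = None,
                        gene_linear_floor: float = 25.0,
                        exon_log2_floor: float = 3.0,
                        ) -> tuple[SummaryMatrix, list[str]]:
    """Run the full preprocessing chain in its fixed order."""
    if bg_params is not None:
        m = background_correct(m, *bg_params)
    else:
        m = background_correct(m)
    if gc_bins is not None:
        m = gc_adjust(m, n_bins=gc_bins)
    m = quantile_normalize_probes(m)
    s = summarize_probesets(m)
    return filter_low_expression(s, gene_linear_floor, exon_log2_floor)
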