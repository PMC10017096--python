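"""Windowed base-pair content, entropy smoothing, thresholding and binning.

The scan proceeds in four stages.  (1) Base-pair content (BPC) — the percent
of double-stranded nucleotides — is computed in a sliding window centred at
each nucleotide; windows truncate at the transcript ends so every position
keeps a value.  (2) Shannon entropy (SE) is smoothed with the local median
over the same windows, ignoring missing positions.  (3) Nucleotides with BPC
strictly above a percentile cutoff of the BPC distribution and smoothed SE
strictly below a percentile cutoff of the SE distribution are flagged as
"structure counts"; by default both cutoffs are the global median.  (4) The
frequency of structure counts — "% structure content" — is tallied in
non-overlapping bins tiling the RNA.

All stages are deterministic: identical inputs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure_io import EntropyTrack, SecondaryStructure

__all__ = [
    "NucleotideProfile",
    "ThresholdSpec",
    "StructureCountMask",
    "ScanResult",
    "compute_bpc",
    "smooth_entropy",
    "resolve_thresholds",
    "structure_counts",
    "bin_structure_content",
    "run_scan",
]

BIN_TABLE_COLUMNS = ["bin_start", "bin_end", "n_counts", "pct_structure_content"]


def _check_window(window: int, n: int) -> int:
    window = int(window)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd positive integer, got {window}")
    if window > 2 * n - 1:
        raise ValueError(f"window {window} exceeds 2N-1 = {2 * n - 1} for N = {n}")
    return window


@dataclass(frozen=True)
class NucleotideProfile:
    """Per-nucleotide windowed BPC (percent, [0, 100]) and median-smoothed SE."""

    bpc: np.ndarray
    se_smooth: np.ndarray  # NaN where no data fell in the window
    window: int

    @property
    def length(self) -> int:
        return self.bpc.size


@dataclass(frozen=True)
class ThresholdSpec:
    """Requested percentiles and the cutoff values they realize on this RNA."""

    bpc_percentile: float
    se_percentile: float
    bpc_cutoff: float
    se_cutoff: float


@dataclass(frozen=True)
class StructureCountMask:
    """Boolean per-nucleotide vector: True where the dual-threshold filter passes."""

    mask: np.ndarray

    @property
    def positions(self) -> np.ndarray:
        """1-based positions of all structure counts."""
        return np.flatnonzero(self.mask) + 1

    @property
    def total(self) -> int:
        return int(self.mask.sum())


def compute_bpc(structure: SecondaryStructure, window: int) -> np.ndarray:
    """Percent of base-paired nucleotides in the truncated window at each position.

    Exact integer arithmetic (cumulative sums of the paired indicator) so the
    result equals the naive per-window count to the last bit.
    """
    n = structure.length
    window = _check_window(window, n)
    h = (window - 1) // 2
    paired = structure.paired.astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(paired)])
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h, n - 1)
    counts = csum[hi + 1] - csum[lo]
    sizes = hi - lo + 1
    return 100.0 * counts / sizes


def smooth_entropy(track: EntropyTrack, window: int) -> np.ndarray:
    """Local median of non-missing SE in the truncated window at each position.

    Positions whose window holds no data stay NaN.
    """
    n = track.length
    window = _check_window(window, n)
    if window == 1:
        return track.values.copy()
    s = pd.Series(track.values)
    # center=True with odd window gives the symmetric [i-h, i+h] window,
    # truncated at the ends by min_periods=1; NaNs are skipped by rolling.
    return (
        s.rolling(window, center=True, min_periods=1).median().to_numpy()
    )


def resolve_thresholds(
    bpc: np.ndarray,
    se_smooth: np.ndarray,
    bpc_percentile: float = 50.0,
    se_percentile: float = 50.0,
) -> ThresholdSpec:
    """Realize percentile cutoffs on the observed BPC and smoothed-SE values.

    Percentiles use linear interpolation between order statistics; missing SE
    values are excluded from the pool.  At the default (50, 50) the cutoffs
    are the global medians.
    """
    for name, p in (("bpc_percentile", bpc_percentile), ("se_percentile", se_percentile)):
        if not 0.0 <= p <= 100.0:
            raise ValueError(f"{name} must be in [0, 100], got {p}")
    bpc = np.asarray(bpc, dtype=np.float64)
    se = np.asarray(se_smooth, dtype=np.float64)
    se_pool = se[~np.isnan(se)]
    if se_pool.size == 0:
        raise ValueError("all smoothed SE values are missing; no SE cutoff derivable")
    if bpc.size == 0:
        raise ValueError("empty BPC vector")
    return ThresholdSpec(
        bpc_percentile=float(bpc_percentile),
        se_percentile=float(se_percentile),
        bpc_cutoff=float(np.percentile(bpc, bpc_percentile)),
        se_cutoff=float(np.percentile(se_pool, se_percentile)),
    )


def structure_counts(
    bpc: np.ndarray, se_smooth: np.ndarray, spec: ThresholdSpec
) -> StructureCountMask:
    """Flag nucleotides with BPC strictly above and SE strictly below the cutoffs.

    A missing smoothed SE can never satisfy "below the cutoff", so such
    positions are never structure counts.
    """
    bpc = np.asarray(bpc, dtype=np.float64)
    se = np.asarray(se_smooth, dtype=np.float64)
    if bpc.size != se.size:
        raise ValueError(f"BPC length {bpc.size} != SE length {se.size}")
    with np.errstate(invalid="ignore"):
        mask = (bpc > spec.bpc_cutoff) & ~np.isnan(se) & (se < spec.se_cutoff)
    return StructureCountMask(mask=mask)


def bin_structure_content(mask: StructureCountMask, bin_size: int) -> pd.DataFrame:
    """Tally structure counts in non-overlapping bins tiling [1, N].

    Returns a DataFrame with columns ``bin_start``, ``bin_end``, ``n_counts``,
    ``pct_structure_content`` in genomic order; the final bin is truncated at N
    and its percentage normalized by its actual length.
    """
    bin_size = int(bin_size)
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    m = mask.mask
    n = m.size
    starts = np.arange(1, n + 1, bin_size)
    ends = np.minimum(starts + bin_size - 1, n)
    counts = np.array([int(m[s - 1 : e].sum()) for s, e in zip(starts, ends)])
    lengths = ends - starts + 1
    return pd.DataFrame(
        {
            "bin_start": starts,
            "bin_end": ends,
            "n_counts": counts,
            "pct_structure_content": 100.0 * counts / lengths,
        }
    )


def rank_bins(table: pd.DataFrame) -> pd.DataFrame:
    """Re-sort a bin table descending by % structure content, ties by bin start."""
    return table.sort_values(
        ["pct_structure_content", "bin_start"], ascending=[False, True]
    ).reset_index(drop=True)


@dataclass(frozen=True)
class ScanResult:
    """All stage outputs of one full scan."""

    profile: NucleotideProfile
    thresholds: ThresholdSpec
    counts: StructureCountMask
    bins: pd.DataFrame
    bin_size: int

    @property
    def ranked_bins(self) -> pd.DataFrame:
        return rank_bins(self.bins)

    def summary(self) -> str:
        """Human-readable run summary: sizes, realized cutoffs, top bins."""
        t = self.thresholds
        lines = [
            f"RNA length:            {self.profile.length} nt",
            f"Sliding window:        {self.profile.window} nt",
            f"Bin size:              {self.bin_size} nt",
            f"BPC cutoff:            {t.bpc_cutoff:.4f} % (p{t.bpc_percentile:g})",
            f"SE cutoff:             {t.se_cutoff:.4f} (p{t.se_percentile:g})",
            f"Structure counts:      {self.counts.total}",
            "",
            "Top bins by % structure content:",
        ]
        top = self.ranked_bins.head(10)
        for row in top.itertuples(index=False):
            lines.append(
                f"  {row.bin_start:>7}-{row.bin_end:<7} "
                f"{row.n_counts:>6} counts  {row.pct_structure_content:6.2f} %"
            )
        return "\n".join(lines)


def run_scan(
    structure: SecondaryStructure,
    entropy: EntropyTrack,
    window: int = 51,
    bin_size: int = 100,
    bpc_percentile: float = 50.0,
    se_percentile: float = 50.0,
) -> ScanResult:
    """Full deterministic scan: profile, thresholds, counts, binned content."""
    if entropy.length != structure.length:
        raise ValueError(
            f"entropy length {entropy.length} != structure length {structure.length}"
        )
    try:
        bpc = compute_bpc(structure, window)
        se_smooth = smooth_entropy(entropy, window)
    except ValueError as e:
        raise ValueError(f"profiling stage: {e}") from e
    try:
        spec = resolve_thresholds(bpc, se_smooth, bpc_percentile, se_percentile)
    except ValueError as e:
        raise ValueError(f"threshold stage: {e}") from e
    mask = structure_counts(bpc, se_smooth, spec)
    try:
        bins = bin_structure_content(mask, bin_size)
    except ValueError as e:
        raise ValueError(f"binning stage: {e}") from e
    profile = NucleotideProfile(bpc=bpc, se_smooth=se_smooth, window=window)
    return ScanResult(
        profile=profile, thresholds=spec, counts=mask, bins=bins, bin_size=bin_size
    )
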