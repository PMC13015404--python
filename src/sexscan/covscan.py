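"""Sex-stratified coverage analysis.

Depth tracks are binned per individual (default 5-kb bins), averaged per
sex, smoothed with centered rolling means, and compared as a log2
male/female ratio with a pseudocount.  Intervals where females show
markedly reduced coverage relative to males (the signature of sequence
present only on the male-limited chromosome) are called from the smoothed
ratio track.  Absolute coverage peaks shared by both sexes (e.g. collapsed
repeats) do not trigger calls because the detector works on the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TRACK_COLUMNS = ["chrom", "start", "end", "depth"]


# ---------------------------------------------------------------------------
# bedGraph I/O


def read_bedgraph(path) -> pd.DataFrame:
    """Read a bedGraph file into columns chrom, start, end, depth."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="t",  # skips an optional "track ..." header line
        header=None,
        names=TRACK_COLUMNS,
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "depth": float},
    )
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    """Write a chrom/start/end/depth frame as bedGraph (0-based half-open)."""
    df.to_csv(path, sep="\t", header=False, index=False, columns=TRACK_COLUMNS)


# ---------------------------------------------------------------------------
# binning and smoothing


def bin_depth(
    positions: np.ndarray,
    depths: np.ndarray,
    chrom: str,
    chrom_length: int,
    bin_size: int = 5000,
) -> pd.DataFrame:
    """Bin per-position depths into fixed windows.

    ``positions`` are 0-based; the bin value is the mean depth over covered
    positions in the bin; bins with no covered position get 0 and are
    flagged with ``empty=True``.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    n_bins = int(np.ceil(chrom_length / bin_size))
    idx = (np.asarray(positions) // bin_size).astype(np.int64)
    if idx.size and (idx.min() < 0 or idx.max() >= n_bins):
        raise ValueError("positions outside chromosome")
    sums = np.bincount(idx, weights=np.asarray(depths, float), minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    starts = np.arange(n_bins, dtype=np.int64) * bin_size
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": np.minimum(starts + bin_size, chrom_length),
            "depth": means,
            "empty": counts == 0,
        }
    )


def rebin_track(track: pd.DataFrame, bin_size: int) -> pd.DataFrame:
    """Re-bin an existing (finer) track to a coarser bin size, per chrom."""
    out = []
    for chrom, grp in track.groupby("chrom", sort=False):
        length = int(grp["end"].max())
        widths = (grp["end"] - grp["start"]).to_numpy(float)
        centers = ((grp["start"] + grp["end"]) // 2).to_numpy()
        idx = (centers // bin_size).astype(np.int64)
        n_bins = int(np.ceil(length / bin_size))
        sums = np.bincount(idx, weights=grp["depth"].to_numpy() * widths, minlength=n_bins)
        wsum = np.bincount(idx, weights=widths, minlength=n_bins)
        means = np.where(wsum > 0, sums / np.maximum(wsum, 1e-300), 0.0)
        starts = np.arange(n_bins, dtype=np.int64) * bin_size
        out.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + bin_size, length),
                    "depth": means,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def rolling_mean(track: pd.DataFrame, span: int, value_col: str = "depth") -> pd.DataFrame:
    """Centered moving average over ``span`` bp (truncated at chrom edges)."""
    out = track.copy()
    smoothed = np.empty(len(track))
    for _, grp in track.groupby("chrom", sort=False):
        bin_size = int((grp["end"] - grp["start"]).iloc[0])
        win = max(1, int(round(span / bin_size)))
        vals = grp[value_col].rolling(win, center=True, min_periods=1).mean()
        smoothed[grp.index.to_numpy()] = vals.to_numpy()
    out[value_col] = smoothed
    return out


# ---------------------------------------------------------------------------
# sex comparison


@dataclass
class CoverageComparison:
    """Per-bin male and female mean depth plus log2 ratio tracks."""

    bins: pd.DataFrame  # chrom, start, end, male_mean, female_mean, log2_ratio
    pseudocount: float
    smoothed: dict[int, pd.DataFrame] | None = None  # span -> frame with log2_ratio


def sex_coverage_ratio(
    male_tracks: list[pd.DataFrame],
    female_tracks: list[pd.DataFrame],
    pseudocount: float = 0.1,
    smooth_spans: tuple[int, ...] = (500_000, 20_000),
) -> CoverageComparison:
    """Mean depth per sex per bin and log2((m+pc)/(f+pc)) ratio track."""
    if not male_tracks or not female_tracks:
        raise ValueError("need at least one track per sex")
    key = male_tracks[0][["chrom", "start", "end"]]

    def _mean(tracks):
        mats = []
        for t in tracks:
            if len(t) != len(key) or not (
                (t["start"].to_numpy() == key["start"].to_numpy()).all()
                and (t["chrom"].to_numpy() == key["chrom"].to_numpy()).all()
            ):
                raise ValueError("track bins do not match")
            mats.append(t["depth"].to_numpy(float))
        return np.mean(mats, axis=0)

    m_mean = _mean(male_tracks)
    f_mean = _mean(female_tracks)
    bins = key.copy()
    bins["male_mean"] = m_mean
    bins["female_mean"] = f_mean
    bins["log2_ratio"] = np.log2((m_mean + pseudocount) / (f_mean + pseudocount))
    smoothed = {}
    for span in smooth_spans:
        sm = bins[["chrom", "start", "end", "log2_ratio"]].copy()
        smoothed[span] = rolling_mean(sm, span, value_col="log2_ratio")
    return CoverageComparison(bins=bins, pseudocount=pseudocount, smoothed=smoothed)


def detect_depleted_intervals(
    cmp: CoverageComparison,
    ratio_min: float = 0.58,
    min_len: int = 20_000,
    smooth_span: int = 20_000,
    max_dropout_bins: int = 1,
) -> pd.DataFrame:
    """Call intervals of female-depleted coverage from the smoothed ratio.

    Maximal runs of bins with smoothed log2(male/female) >= ratio_min are
    reported when at least ``min_len`` long; runs separated by at most
    ``max_dropout_bins`` sub-threshold bins are merged.  Returns a BED-style
    frame (0-based half-open).
    """
    if cmp.smoothed and smooth_span in cmp.smoothed:
        track = cmp.smoothed[smooth_span]
    else:
        track = rolling_mean(
            cmp.bins[["chrom", "start", "end", "log2_ratio"]],
            smooth_span,
            value_col="log2_ratio",
        )
    rows = []
    for chrom, grp in track.groupby("chrom", sort=False):
        above = grp["log2_ratio"].to_numpy() >= ratio_min
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        runs = _runs(above, max_dropout_bins)
        for i0, i1 in runs:
            s, e = int(starts[i0]), int(ends[i1])
            if e - s >= min_len:
                mean_ratio = float(grp["log2_ratio"].to_numpy()[i0 : i1 + 1].mean())
                rows.append((chrom, s, e, mean_ratio))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_log2_ratio"])


def _runs(mask: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """Maximal index runs of True, bridging gaps of at most max_gap False."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > max_gap + 1)
    starts = np.r_[0, breaks + 1]
    ends = np.r_[breaks, idx.size - 1]
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]
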