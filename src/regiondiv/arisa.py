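"""ARISA fragment-length binning with a sliding binning frame.

Electropherogram peaks from different samples drift by fractions of a
nucleotide, so fixed-width bins (window 1.5 nt) are laid out in several
candidate frames offset by multiples of the shift (0.3 nt, giving five
frames at the defaults).  The frame whose relative-fluorescence profiles
correlate best across samples (mean pairwise Pearson r) is selected;
per-sample richness is the number of occupied bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import PeakProfile

__all__ = ["BinnedFingerprint", "bin_peaks", "arisa_richness"]


@dataclass
class BinnedFingerprint:
    frame_offset: float
    window: float
    bin_edges: np.ndarray           # increasing, width == window
    table: pd.DataFrame             # samples x bins, relative fluorescence
    frame_scores: dict[float, float]

    def richness(self) -> dict[str, int]:
        return {s: int((self.table.loc[s] > 0).sum())
                for s in self.table.index}


def _assign_bins(profiles, window: float, offset: float):
    """(sample, bin index) -> summed fluorescence for one frame."""
    rows = {}
    for prof in profiles:
        idx = np.floor((prof.fragment_lengths - offset) / window).astype(int)
        agg: dict[int, float] = {}
        for b, f in zip(idx, prof.fluorescences):
            agg[int(b)] = agg.get(int(b), 0.0) + float(f)
        rows[prof.sample_id] = agg
    return rows


def _frame_table(rows, samples) -> pd.DataFrame:
    bins = sorted({b for agg in rows.values() for b in agg})
    mat = np.zeros((len(samples), len(bins)))
    pos = {b: j for j, b in enumerate(bins)}
    for i, s in enumerate(samples):
        for b, f in rows[s].items():
            mat[i, pos[b]] = f
    totals = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        mat = np.where(totals > 0, mat / np.maximum(totals, 1e-300), 0.0)
    return pd.DataFrame(mat, index=samples, columns=bins)


def _mean_pairwise_correlation(table: pd.DataFrame) -> float:
    mat = table.to_numpy()
    n = mat.shape[0]
    if n < 2:
        return 0.0
    sd = mat.std(axis=1)
    keep = sd > 0
    if keep.sum() < 2:
        return 0.0
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(mat[keep])
    iu = np.triu_indices(corr.shape[0], k=1)
    return float(np.nanmean(corr[iu]))


def bin_peaks(profiles: list[PeakProfile], window: float = 1.5,
              shift: float = 0.3,
              fluorescence_floor: float = 0.0) -> BinnedFingerprint:
    """Bin peaks in every candidate frame and keep the best frame.

    ``window / shift`` must be integral (5 frames at the defaults).
    Within a (sample, bin) cell fluorescences are summed, then each
    sample's fluorescence is normalised to relative values.  Frame
    selection maximises the mean pairwise Pearson correlation of the
    relative-fluorescence profiles across samples; ties go to the lowest
    offset.  With a single sample the objective is degenerate and the
    first frame is returned with a warning.
    """
    if not profiles:
        raise ValueError("no peak profiles to bin")
    if window <= 0 or not 0 < shift <= window:
        raise ValueError("need window > 0 and 0 < shift <= window")
    n_frames_f = window / shift
    n_frames = int(round(n_frames_f))
    if abs(n_frames_f - n_frames) > 1e-9:
        raise ValueError("window/shift must be an integer number of frames")
    if fluorescence_floor > 0:
        profiles = [
            PeakProfile(
                sample_id=p.sample_id,
                fragment_lengths=p.fragment_lengths[
                    p.fluorescences >= fluorescence_floor],
                fluorescences=p.fluorescences[
                    p.fluorescences >= fluorescence_floor],
            ) for p in profiles
        ]
    samples = [p.sample_id for p in profiles]
    if len(samples) != len(set(samples)):
        raise ValueError("duplicate sample ids in profiles")
    if len(samples) < 2:
        warnings.warn("single sample: frame selection is degenerate; "
                      "using the first frame", stacklevel=2)

    best = None
    scores: dict[float, float] = {}
    for k in range(n_frames):
        offset = k * shift
        rows = _assign_bins(profiles, window, offset)
        table = _frame_table(rows, samples)
        score = _mean_pairwise_correlation(table)
        scores[round(offset, 10)] = score
        if best is None or score > best[0] + 1e-12:
            best = (score, offset, table)
    _, offset, table = best
    bin_idx = np.asarray(sorted(table.columns))
    edges = offset + np.append(bin_idx * window, (bin_idx[-1] + 1) * window) \
        if bin_idx.size else np.array([offset])
    return BinnedFingerprint(frame_offset=float(offset), window=float(window),
                             bin_edges=edges, table=table,
                             frame_scores=scores)


def arisa_richness(fp: BinnedFingerprint) -> dict[str, int]:
    """Per-sample count of bins with relative fluorescence > 0."""
    return fp.richness()
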