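"""Co-translational assembly scoring by one-breakpoint step-function fitting.

A factor that binds ribosomes once its interaction partner's domain emerges
from the exit tunnel leaves a characteristic footprint signature: the ratio
of selective (factor-IP) to total 80S footprints is low over the 5' part of
the CDS and jumps at the codon where binding becomes possible. The analysis
bins that ratio along the CDS scaled 0-100%, fits a one-step (piecewise
constant, single breakpoint) function by least squares, and reports the
step height — the *co-translational assembly score*:

    score = mean(ratio[b:]) - mean(ratio[:b])

with b the breakpoint minimizing the total sum of squared residuals over
all possible breakpoints. Positive scores mean binding increases along the
message.

``fit_step`` is the direct exhaustive search (every breakpoint, means and
SSE per side); ``fit_step_fast`` is an algebraically identical linear-time
version using prefix sums of x and x^2. Ties in SSE are broken toward the
smallest breakpoint index for determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import FootprintTrack, TranscriptModel, detected_transcripts

CPM = 1e6  # depth normalization scale: counts per million assigned reads


def depth_matched_ratio(num_raw, den_raw, num_size: int, den_size: int,
                        pseudocount: float = 0.5):
    """Depth-normalized ratio with a pseudocount in read units.

    Both count vectors are rescaled to the shallower library's depth, so
    one sequenced read in the smaller library keeps weight ~1 and the
    pseudocount (default half a read) bounds ratios on sparse bins without
    biasing the flat case. Returns (num*c_n + pc) / (den*c_d + pc) with
    c_i = min(sizes)/size_i.
    """
    ref = min(max(num_size, 1), max(den_size, 1))
    num = np.asarray(num_raw, dtype=float) * (ref / max(num_size, 1))
    den = np.asarray(den_raw, dtype=float) * (ref / max(den_size, 1))
    return (num + pseudocount) / (den + pseudocount)


@dataclass
class RatioProfile:
    """Binned selective/total ratio along a CDS scaled 0-100%."""

    transcript_id: str
    values: np.ndarray  # length n_bins, finite, >= 0
    bin_edges: np.ndarray  # n_bins+1 nt positions (transcript coords)
    coverage: np.ndarray  # raw total-library counts per bin
    pseudocount: float
    usable: bool = True  # False when the total library covers no bin

    @property
    def n_bins(self) -> int:
        return len(self.values)


@dataclass
class StepFit:
    """Best one-breakpoint step fit to a profile.

    The left segment covers bins [0, breakpoint), the right segment
    [breakpoint, n). ``score`` is mean_right - mean_left.
    """

    breakpoint: int
    mean_left: float
    mean_right: float
    sse: float

    @property
    def score(self) -> float:
        return self.mean_right - self.mean_left

    def summary(self) -> str:
        return (f"StepFit(breakpoint={self.breakpoint}, "
                f"mean_left={self.mean_left:.4f}, mean_right={self.mean_right:.4f}, "
                f"score={self.score:.4f}, sse={self.sse:.4f})")


#: relative tolerance for treating two breakpoint SSEs as tied; scaled by the
#: profile's sum of squares so exact symmetric ties resolve identically in the
#: direct and the prefix-sum implementation
_SSE_RTOL = 1e-9


def _check_profile(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("profile must be a 1-D vector of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("profile contains non-finite values")
    return x


def fit_step(profile: np.ndarray) -> StepFit:
    """Exhaustive one-breakpoint least-squares step fit.

    Every interior position b in [1, n-1] is tried as a breakpoint; the
    side means and the summed squared residuals are computed directly; the
    breakpoint with the least SSE wins (smallest b on ties).
    """
    x = _check_profile(profile)
    n = len(x)
    fits = []
    for b in range(1, n):
        left, right = x[:b], x[b:]
        ml, mr = float(left.mean()), float(right.mean())
        sse = float(((left - ml) ** 2).sum() + ((right - mr) ** 2).sum())
        fits.append(StepFit(breakpoint=b, mean_left=ml, mean_right=mr, sse=sse))
    best_sse = min(f.sse for f in fits)
    # ties (exact or within rounding) resolve to the smallest breakpoint
    tol = _SSE_RTOL * (1.0 + float(np.sum(x * x)))
    return next(f for f in fits if f.sse <= best_sse + tol)


def fit_step_fast(profile: np.ndarray) -> StepFit:
    """Linear-time step fit via prefix sums; identical contract to fit_step.

    For a candidate breakpoint b the segment SSE is
    sum(x^2) - (sum x)^2 / len, computed for both sides from running sums.
    """
    x = _check_profile(profile)
    n = len(x)
    s = np.cumsum(x)
    s2 = np.cumsum(x * x)
    total, total2 = s[-1], s2[-1]
    b = np.arange(1, n)
    left_sum = s[:-1]
    left_sum2 = s2[:-1]
    right_sum = total - left_sum
    right_sum2 = total2 - left_sum2
    sse = (left_sum2 - left_sum ** 2 / b) + (right_sum2 - right_sum ** 2 / (n - b))
    sse = np.maximum(sse, 0.0)  # clamp tiny negative rounding
    tol = _SSE_RTOL * (1.0 + float(total2))
    i = int(np.flatnonzero(sse <= sse.min() + tol)[0])  # smallest b on (near-)ties
    bb = int(b[i])
    return StepFit(
        breakpoint=bb,
        mean_left=float(left_sum[i] / bb),
        mean_right=float(right_sum[i] / (n - bb)),
        sse=float(sse[i]),
    )


def compute_ratio_profile(selective: FootprintTrack, total: FootprintTrack,
                          transcript: TranscriptModel, n_bins: int = 100,
                          pseudocount: float = 0.5) -> RatioProfile:
    """Bin the depth-normalized selective/total ratio over the CDS.

    The CDS is partitioned into ``n_bins`` near-equal nucleotide bins
    (scaling its length to 0-100%); per-bin sums are depth-matched to the
    shallower library (see ``depth_matched_ratio``) before the
    pseudocounted ratio is formed. Bins without any coverage resolve to
    the neutral pseudocount ratio of 1, keeping bin indices comparable
    across genes.
    """
    cds = transcript.cds
    if cds.length < n_bins:
        warnings.warn(
            f"{transcript.transcript_id}: CDS of {cds.length} nt shorter than "
            f"{n_bins} bins; falling back to per-nt bins")
        n_bins = cds.length
    edges = np.round(np.linspace(cds.start, cds.end, n_bins + 1)).astype(int)
    rel = edges - cds.start
    sel = selective.vector(transcript.transcript_id)[cds.start:cds.end].astype(float)
    tot = total.vector(transcript.transcript_id)[cds.start:cds.end].astype(float)
    sel_sums = np.add.reduceat(sel, rel[:-1])
    tot_sums = np.add.reduceat(tot, rel[:-1])
    values = depth_matched_ratio(sel_sums, tot_sums, selective.library_size,
                                 total.library_size, pseudocount)
    usable = bool(tot_sums.sum() > 0)
    return RatioProfile(
        transcript_id=transcript.transcript_id,
        values=values,
        bin_edges=edges,
        coverage=tot_sums.astype(int),
        pseudocount=pseudocount,
        usable=usable,
    )


def score_all_genes(selective, total, transcripts, n_bins: int = 100,
                    pseudocount: float = 0.5, min_counts: int = 32,
                    apply_detection: bool = True) -> pd.DataFrame:
    """Assembly scores for all detected genes, sorted best first.

    ``selective`` and ``total`` may be single tracks or equal-length lists
    of biological replicates; per-replicate scores are averaged, as are the
    fitted means and breakpoints.
    """
    sel_reps = selective if isinstance(selective, (list, tuple)) else [selective]
    tot_reps = total if isinstance(total, (list, tuple)) else [total]
    if len(sel_reps) != len(tot_reps):
        raise ValueError("selective and total replicate lists differ in length")
    if apply_detection:
        keep = set(detected_transcripts(transcripts, tot_reps, min_counts=min_counts))
        transcripts = [t for t in transcripts if t.transcript_id in keep]
    rows = []
    for t in transcripts:
        fits, covs, bnts = [], [], []
        usable = True
        for sel, tot in zip(sel_reps, tot_reps):
            prof = compute_ratio_profile(sel, tot, t, n_bins=n_bins,
                                         pseudocount=pseudocount)
            if not prof.usable:
                usable = False
                break
            fit = fit_step_fast(prof.values)
            fits.append(fit)
            covs.append(int(prof.coverage.sum()))
            bnts.append(int(prof.bin_edges[fit.breakpoint] - t.cds.start))
        if not usable or not fits:
            continue
        rows.append({
            "transcript_id": t.transcript_id,
            "score": float(np.mean([f.score for f in fits])),
            "breakpoint_bin": float(np.mean([f.breakpoint for f in fits])),
            "breakpoint_nt": float(np.mean(bnts)),
            "mean_left": float(np.mean([f.mean_left for f in fits])),
            "mean_right": float(np.mean([f.mean_right for f in fits])),
            "sse": float(np.mean([f.sse for f in fits])),
            "coverage": int(np.mean(covs)),
        })
    df = pd.DataFrame(rows, columns=["transcript_id", "score", "breakpoint_bin",
                                     "breakpoint_nt", "mean_left", "mean_right",
                                     "sse", "coverage"])
    return df.sort_values("score", ascending=False, kind="mergesort").reset_index(drop=True)
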