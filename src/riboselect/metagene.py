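"""Anchor-aligned metagene profiles with depth and scanning normalization.

A metagene aggregates footprint signal across many transcripts aligned at a
common anchor codon (main-ORF start/stop or uORF start/stop) as a function
of nucleotide offset. uORF anchors are restricted to translated,
AUG-initiated uORFs whose intercistronic space (uORF stop to main-ORF
start) is at least 80 nt, so signal at the uORF stop is not confounded by
initiation on the main ORF.

Two normalizations are supported, matching how 80S and 40S libraries are
comparable across samples:

* 80S: divide by library sequencing depth (counts per million);
* 40S: rescale each library so the summed scanning signal in a window
  upstream of the start codon (default -100..-80 nt) is equal across
  libraries — conditions are then compared at equal scanning flux.

A centered moving average of window 3 removes triplet periodicity; the
window shrinks symmetrically at the edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import numpy.ma as ma

from .tracks import FootprintTrack, TranscriptModel

ANCHORS = ("morf_start", "morf_stop", "uorf_start", "uorf_stop")


@dataclass
class MetageneProfile:
    anchor: str
    offsets: np.ndarray  # nt offsets relative to the anchor
    values: np.ndarray  # per-offset mean over contributing transcripts
    n_per_offset: np.ndarray  # contributing (unmasked) anchors per offset
    n_features: int  # anchors aggregated
    normalization: dict = field(default_factory=dict)
    smoothing_window: int = 1

    def copy_with(self, values: np.ndarray, **norm) -> "MetageneProfile":
        return MetageneProfile(
            anchor=self.anchor,
            offsets=self.offsets,
            values=np.asarray(values, dtype=float),
            n_per_offset=self.n_per_offset,
            n_features=self.n_features,
            normalization={**self.normalization, **norm},
            smoothing_window=self.smoothing_window,
        )


def _anchor_positions(transcript: TranscriptModel, anchor: str,
                      total_80s: FootprintTrack | None,
                      min_intercistronic: int, min_uorf_reads: int) -> list[int]:
    if anchor == "morf_start":
        return [transcript.cds.start]
    if anchor == "morf_stop":
        return [transcript.cds.end - 3]
    positions = []
    for u in transcript.uorfs:
        if u.start_codon != "ATG":
            continue
        if transcript.cds.start - u.stop_end < min_intercistronic:
            continue
        if total_80s is not None:
            from .uorfs import classify_translated

            if not classify_translated(u, total_80s, transcript.transcript_id,
                                       min_reads=min_uorf_reads):
                continue
        positions.append(u.start if anchor == "uorf_start" else u.stop_end - 3)
    return positions


def collect_anchored(track: FootprintTrack, transcripts: Sequence[TranscriptModel],
                     anchor: str, window: tuple[int, int] = (-100, 200),
                     uorf_filter_track: FootprintTrack | None = None,
                     min_intercistronic: int = 80,
                     min_uorf_reads: int = 1) -> ma.MaskedArray:
    """Per-anchor matrix of counts at offsets [window[0], window[1]).

    Rows are anchors, columns offsets; offsets falling outside a
    transcript are masked. uORF anchors apply the translated + AUG +
    intercistronic >= ``min_intercistronic`` nt filters, with translation
    judged on ``uorf_filter_track`` (a total 80S library).
    """
    if anchor not in ANCHORS:
        raise ValueError(f"unknown anchor {anchor!r}; expected one of {ANCHORS}")
    lo, hi = window
    if lo >= hi:
        raise ValueError("empty metagene window")
    rows = []
    for t in transcripts:
        vec = track.vector(t.transcript_id)
        for pos in _anchor_positions(t, anchor, uorf_filter_track,
                                     min_intercistronic, min_uorf_reads):
            row = np.zeros(hi - lo, dtype=float)
            mask = np.ones(hi - lo, dtype=bool)
            a = max(0, pos + lo)
            b = min(len(vec), pos + hi)
            if a < b:
                row[a - (pos + lo):b - (pos + lo)] = vec[a:b]
                mask[a - (pos + lo):b - (pos + lo)] = False
            rows.append(ma.MaskedArray(row, mask=mask))
    if not rows:
        raise ValueError(
            f"no anchors left for {anchor!r} after filters "
            f"(AUG-initiated, translated, intercistronic >= {min_intercistronic} nt)")
    return ma.stack(rows)


def metagene_profile(track: FootprintTrack, transcripts: Sequence[TranscriptModel],
                     anchor: str, window: tuple[int, int] = (-100, 200),
                     **kwargs) -> MetageneProfile:
    """Collect anchors and aggregate by the per-offset mean over unmasked rows."""
    matrix = collect_anchored(track, transcripts, anchor, window=window, **kwargs)
    n_per_offset = (~matrix.mask).sum(axis=0)
    values = matrix.mean(axis=0).filled(0.0)
    return MetageneProfile(
        anchor=anchor,
        offsets=np.arange(window[0], window[1]),
        values=np.asarray(values, dtype=float),
        n_per_offset=np.asarray(n_per_offset, dtype=int),
        n_features=matrix.shape[0],
        normalization={},
    )


def normalize_80s(profiles: dict[str, MetageneProfile],
                  library_sizes: dict[str, int]) -> dict[str, MetageneProfile]:
    """Scale each 80S profile to counts per million library reads."""
    out = {}
    for lib, prof in profiles.items():
        size = library_sizes[lib]
        if size <= 0:
            raise ValueError(f"library {lib!r} has zero size")
        out[lib] = prof.copy_with(prof.values * 1e6 / size,
                                  library_size=size, scale="per_million")
    return out


def normalize_scanning(profiles: dict[str, MetageneProfile],
                       scan_window: tuple[int, int] = (-100, -80)
                       ) -> dict[str, MetageneProfile]:
    """Equalize the scanning-ribosome signal upstream of the start codon.

    Each 40S library is rescaled so its summed signal over ``scan_window``
    (offsets relative to the anchor, half-open) matches the first
    library's; comparisons between conditions are then at matched
    scanning flux.
    """
    libs = list(profiles)
    sums = {}
    for lib in libs:
        prof = profiles[lib]
        sel = (prof.offsets >= scan_window[0]) & (prof.offsets < scan_window[1])
        if not sel.any():
            raise ValueError("scan_window lies outside the metagene window")
        s = float(prof.values[sel].sum())
        if s <= 0:
            raise ValueError(f"library {lib!r} has no scanning signal in {scan_window}")
        sums[lib] = s
    ref = sums[libs[0]]
    return {
        lib: profiles[lib].copy_with(profiles[lib].values * (ref / sums[lib]),
                                     scanning_window=scan_window,
                                     scanning_factor=ref / sums[lib])
        for lib in libs
    }


def smooth(values: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average; the window shrinks symmetrically at edges.

    A window of 3 removes the triplet periodicity of elongating-ribosome
    footprints; window 1 is the identity.
    """
    if window < 1:
        raise ValueError("smoothing window must be >= 1")
    x = np.asarray(values, dtype=float)
    n = len(x)
    half = (window - 1) // 2
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = x[i - h:i + h + 1].mean()
    return out


def smooth_profile(profile: MetageneProfile, window: int = 3) -> MetageneProfile:
    out = profile.copy_with(smooth(profile.values, window))
    out.smoothing_window = window
    return out


def plot_profiles(profiles: dict[str, MetageneProfile], path=None, window: int = 3):
    """Plot smoothed traces over shaded raw (periodicity-bearing) data.

    Returns the matplotlib figure; writes it to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for label, prof in profiles.items():
        (line,) = ax.plot(prof.offsets, smooth(prof.values, window), label=label)
        ax.fill_between(prof.offsets, prof.values, alpha=0.25,
                        color=line.get_color(), linewidth=0)
    anchor = next(iter(profiles.values())).anchor
    ax.axvline(0, color="grey", linestyle=":", linewidth=1)
    ax.set_xlabel(f"offset from {anchor} (nt)")
    ax.set_ylabel("normalized footprint signal")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
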