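"""uORF detection, translated-uORF classification, and enrichment statistics.

An upstream ORF (uORF) is an AUG-initiated reading frame in the 5'UTR whose
stop codon lies at or before the main-ORF start; an overlapping ORF (oORF)
starts in the 5'UTR but runs past the main start codon (including the case
where its stop codon straddles it — a ribosome terminating downstream of
the main start cannot have initiated the main ORF). Near-cognate starts
(single-mismatch variants of AUG) can optionally be scanned as well.

A uORF counts as *translated* under a deliberately low-stringency rule:
at least one 80S footprint assigned within it (threshold configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import (
    NEAR_COGNATE_STARTS,
    STOP_CODONS,
    FootprintTrack,
    TranscriptModel,
    UORF,
    region_sum,
)

CATEGORIES = ("no_uorf", "uorf_untranslated", "uorf_translated")


class UorfScan(NamedTuple):
    uorfs: list[UORF]
    oorfs: list[UORF]  # stop_end marks the first in-frame stop (or transcript end)


def find_uorfs(transcript: TranscriptModel, allow_near_cognate: bool = False) -> UorfScan:
    """Scan the 5'UTR 5'->3' for upstream and overlapping ORFs.

    Every qualifying start is reported, including overlapping and nested
    ORFs; no masking is applied.
    """
    if transcript.sequence is None:
        raise ValueError(f"{transcript.transcript_id}: sequence required to scan for uORFs")
    seq = transcript.sequence.upper()
    cds_start = transcript.cds.start
    starts = ("ATG",) + (NEAR_COGNATE_STARTS if allow_near_cognate else ())
    uorfs, oorfs = [], []
    for s in range(cds_start):
        codon = seq[s:s + 3]
        if codon not in starts:
            continue
        stop_end = None
        for p in range(s + 3, len(seq) - 2, 3):
            if seq[p:p + 3] in STOP_CODONS:
                stop_end = p + 3
                break
        orf = UORF(start=s, stop_end=stop_end if stop_end is not None else len(seq),
                   frame=s % 3, start_codon=codon)
        if stop_end is not None and stop_end <= cds_start:
            uorfs.append(orf)
        else:
            oorfs.append(orf)
    return UorfScan(uorfs=uorfs, oorfs=oorfs)


def annotate_uorfs(transcripts: Sequence[TranscriptModel],
                   allow_near_cognate: bool = False) -> None:
    """Populate each transcript's ``uorfs`` list in place from its sequence."""
    for t in transcripts:
        t.uorfs = find_uorfs(t, allow_near_cognate=allow_near_cognate).uorfs


def classify_translated(uorf: UORF, total_80s: FootprintTrack, transcript_id: str,
                        min_reads: int = 1) -> bool:
    """Low-stringency translated call: >= min_reads 80S footprints in the uORF."""
    return region_sum(total_80s, transcript_id, (uorf.start, uorf.stop_end)) >= min_reads


def categorize_transcripts(transcripts: Sequence[TranscriptModel],
                           total_80s: FootprintTrack,
                           min_reads: int = 1) -> dict[str, str]:
    """Partition transcripts into no_uorf / uorf_untranslated / uorf_translated.

    A transcript lands in ``uorf_translated`` as soon as one of its
    annotated uORFs carries 80S footprints; transcripts with uORFs but no
    footprints on any of them are ``uorf_untranslated``.
    """
    labels = {}
    for t in transcripts:
        if not t.uorfs:
            labels[t.transcript_id] = "no_uorf"
            continue
        translated = False
        for u in t.uorfs:
            u.translated = classify_translated(u, total_80s, t.transcript_id,
                                               min_reads=min_reads)
            translated = translated or u.translated
        labels[t.transcript_id] = "uorf_translated" if translated else "uorf_untranslated"
    return labels


@dataclass
class UorfEnrichmentResult:
    """Rank-sum comparison of per-gene uORF counts between two gene sets."""

    n_target: int
    n_background: int
    mean_target: float
    mean_background: float
    ci_target: tuple[float, float]  # normal-approximation 95% CI on the mean
    ci_background: tuple[float, float]
    statistic: float  # Mann-Whitney U of the target group
    p_value: float
    histogram: pd.DataFrame  # uORF-count frequency per group


def _mean_ci(x: np.ndarray) -> tuple[float, float]:
    m = float(np.mean(x))
    half = 1.96 * float(np.std(x, ddof=1)) / np.sqrt(len(x)) if len(x) > 1 else 0.0
    return (m - half, m + half)


def uorf_count_enrichment(target_genes: Sequence[str], background_genes: Sequence[str],
                          uorf_counts: Mapping[str, int]) -> UorfEnrichmentResult:
    """Two-sided Mann-Whitney test of uORF counts, target vs background genes."""
    if set(target_genes) & set(background_genes):
        raise ValueError("target and background gene sets must be disjoint")
    tx = np.array([uorf_counts[g] for g in target_genes], dtype=float)
    bx = np.array([uorf_counts[g] for g in background_genes], dtype=float)
    if len(tx) == 0 or len(bx) == 0:
        raise ValueError("both gene groups must be nonempty")
    res = stats.mannwhitneyu(tx, bx, alternative="two-sided")
    hist_rows = []
    for label, arr in (("target", tx), ("background", bx)):
        vals, freqs = np.unique(arr.astype(int), return_counts=True)
        for v, f in zip(vals, freqs):
            hist_rows.append({"group": label, "n_uorfs": int(v),
                              "n_genes": int(f), "fraction": f / len(arr)})
    return UorfEnrichmentResult(
        n_target=len(tx),
        n_background=len(bx),
        mean_target=float(tx.mean()),
        mean_background=float(bx.mean()),
        ci_target=_mean_ci(tx),
        ci_background=_mean_ci(bx),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        histogram=pd.DataFrame(hist_rows),
    )


@dataclass
class OverlapTestResult:
    universe_size: int
    size_a: int
    size_b: int
    observed_overlap: int
    p_value: float  # upper-tail binomial probability of >= observed overlap


def overlap_significance(set_a, set_b, universe_size: int) -> OverlapTestResult:
    """Binomial test for the overlap between two gene sets.

    Drawing |A| genes that each hit B with probability |B|/universe, the
    p-value is P(X >= observed overlap) for X ~ Binomial(|A|, |B|/universe).
    """
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("set sizes exceed the universe")
    observed = len(a & b)
    if observed > min(len(a), len(b)):  # unreachable for true sets; guards count input
        raise ValueError("overlap exceeds the smaller set")
    p = float(stats.binom.sf(observed - 1, len(a), len(b) / universe_size))
    return OverlapTestResult(
        universe_size=universe_size,
        size_a=len(a),
        size_b=len(b),
        observed_overlap=observed,
        p_value=p,
    )
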