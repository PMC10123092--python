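"""Per-gene selective-binding and translation-efficiency statistics.

The binding ratio of a gene is the depth-normalized selective 40S footprint
sum over its 5'UTR divided by the matched total 40S sum — a per-gene
measure of how strongly the IPed factor rides on scanning ribosomes of that
message. Heterogeneous factors (unlike canonical initiation factors, which
bind all messages about equally) give broad or multimodal ratio
distributions; genes are ranked into top/bottom deciles and compared across
uORF categories with Kruskal-Wallis plus Dunn's post-hoc test.

Translation efficiency (TE) is the depth-normalized 80S CDS footprint sum
over the depth-normalized mRNA count; log2 ΔTE compares a treated
(e.g. factor-depleted) condition against control. Binding is related to
ΔTE by rank correlation (ratios are heavy-tailed, so Spearman rather than
Pearson).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import FootprintTrack, TranscriptModel
from .assembly import CPM


@dataclass
class GeneBindingStat:
    gene_id: str
    binding_ratio: float
    coverage: int  # raw total 40S counts in the 5'UTR
    decile: str | None = None  # top10 | bottom10 | mid


def binding_ratio_per_gene(selective_40s: FootprintTrack, total_40s: FootprintTrack,
                           transcripts: Sequence[TranscriptModel],
                           pseudocount: float = 0.5) -> list[GeneBindingStat]:
    """Selective/total 40S ratio over each gene's 5'UTR, CPM scale + pseudocount.

    Gene-level 5'UTR sums are large enough that the CPM-scale pseudocount
    only guards the zero-count edge; the ratio is exactly invariant to
    rescaling either library's counts.
    """
    sel_size = max(selective_40s.library_size, 1)
    tot_size = max(total_40s.library_size, 1)
    out = []
    for t in transcripts:
        s, e = t.utr5
        raw_sel = int(selective_40s.vector(t.transcript_id)[s:e].sum())
        raw_tot = int(total_40s.vector(t.transcript_id)[s:e].sum())
        ratio = (raw_sel * CPM / sel_size + pseudocount) / \
            (raw_tot * CPM / tot_size + pseudocount)
        out.append(GeneBindingStat(gene_id=t.transcript_id, binding_ratio=float(ratio),
                                   coverage=raw_tot))
    return out


def decile_groups(stats_list: Sequence[GeneBindingStat],
                  fraction: float = 0.1) -> pd.DataFrame:
    """Label the top and bottom ``fraction`` of genes by binding ratio.

    Group size is floor(fraction * n); ties in the ratio are broken by
    gene_id so the grouping is deterministic. Labels top/bottom/mid
    partition the gene set.
    """
    if not (0 < fraction <= 0.5):
        raise ValueError("fraction must lie in (0, 0.5]")
    n = len(stats_list)
    k = int(math.floor(fraction * n))
    if k < 1:
        raise ValueError(f"{n} genes at fraction {fraction} give an empty group")
    order = sorted(stats_list, key=lambda s: (-s.binding_ratio, s.gene_id))
    for i, s in enumerate(order):
        if i < k:
            s.decile = "top10"
        elif i >= n - k:
            s.decile = "bottom10"
        else:
            s.decile = "mid"
    return pd.DataFrame({
        "gene_id": [s.gene_id for s in order],
        "binding_ratio": [s.binding_ratio for s in order],
        "decile": [s.decile for s in order],
    })


@dataclass
class CategoryComparison:
    """Kruskal-Wallis omnibus plus Dunn pairwise tests across uORF categories."""

    group_sizes: dict[str, int]
    group_medians: dict[str, float]
    statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, z, p_raw, p_adjusted


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's z-tests on pooled midranks with tie correction; Bonferroni over pairs."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_rank = {}
    idx = 0
    for g in labels:
        k = len(groups[g])
        mean_rank[g] = float(ranks[idx:idx + k].mean())
        idx += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (12 * (n_total - 1))) \
        if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    pairs = list(combinations(labels, 2))
    for a, b in pairs:
        se = math.sqrt(var_base * (1 / len(groups[a]) + 1 / len(groups[b])))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p,
                     "p_adjusted": min(1.0, p * len(pairs))})
    return pd.DataFrame(rows)


def compare_binding_by_uorf_category(stats_list: Sequence[GeneBindingStat],
                                     categories: Mapping[str, str]) -> CategoryComparison:
    """Compare binding ratios across uORF categories.

    Omnibus: Kruskal-Wallis H (scipy); pairwise: Dunn's z-tests with
    Bonferroni adjustment over the pairs.
    """
    groups: dict[str, list[float]] = {}
    for s in stats_list:
        if s.gene_id in categories:
            groups.setdefault(categories[s.gene_id], []).append(s.binding_ratio)
    if len(groups) < 2:
        raise ValueError("need at least two nonempty categories")
    if any(len(v) == 0 for v in groups.values()):
        raise ValueError("empty category")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if np.ptp(np.concatenate(list(arrays.values()))) == 0:
        h, p = 0.0, 1.0  # all values identical: no rank variation
    else:
        h, p = stats.kruskal(*arrays.values())
    return CategoryComparison(
        group_sizes={g: len(v) for g, v in arrays.items()},
        group_medians={g: float(np.median(v)) for g, v in arrays.items()},
        statistic=float(h),
        p_value=float(p),
        pairwise=_dunn_pairwise(arrays),
    )


@dataclass
class TEResult:
    gene_id: str
    te_control: float
    te_treated: float
    log2_dte: float


def translation_efficiency(total_80s: Mapping[str, FootprintTrack],
                           rna_counts: Mapping[str, Mapping[str, int]],
                           transcripts: Sequence[TranscriptModel],
                           conditions: tuple[str, str] = ("control", "knockdown"),
                           pseudocount: float = 0.5) -> list[TEResult]:
    """Per-gene TE (80S CDS CPM / mRNA CPM) and log2 ΔTE treated vs control.

    ``total_80s`` and ``rna_counts`` map condition labels to an 80S track
    and a gene->count table respectively; genes without RNA counts in
    either condition are skipped with a warning.
    """
    ctrl, treat = conditions
    for c in conditions:
        if c not in total_80s or c not in rna_counts:
            raise ValueError(f"missing condition {c!r} in inputs")
    fp_sizes = {c: max(total_80s[c].library_size, 1) for c in conditions}
    rna_sizes = {c: max(sum(rna_counts[c].values()), 1) for c in conditions}

    def te(cond: str, t: TranscriptModel) -> float | None:
        if t.transcript_id not in rna_counts[cond]:
            return None
        fp = int(total_80s[cond].vector(t.transcript_id)[t.cds.start:t.cds.end].sum())
        fp_cpm = fp * CPM / fp_sizes[cond]
        rna_cpm = rna_counts[cond][t.transcript_id] * CPM / rna_sizes[cond]
        return (fp_cpm + pseudocount) / (rna_cpm + pseudocount)

    out = []
    for t in transcripts:
        te_c, te_t = te(ctrl, t), te(treat, t)
        if te_c is None or te_t is None:
            warnings.warn(f"{t.transcript_id}: missing RNA counts, skipped")
            continue
        out.append(TEResult(gene_id=t.transcript_id, te_control=te_c, te_treated=te_t,
                            log2_dte=float(np.log2(te_t / te_c))))
    return out


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    table: pd.DataFrame  # gene_id, binding_ratio, log2_dte


def correlate_binding_vs_dte(stats_list: Sequence[GeneBindingStat],
                             te_results: Sequence[TEResult]) -> CorrelationResult:
    """Spearman correlation between 40S binding ratio and log2 ΔTE."""
    binding = {s.gene_id: s.binding_ratio for s in stats_list}
    rows = [(r.gene_id, binding[r.gene_id], r.log2_dte)
            for r in te_results if r.gene_id in binding]
    if len(rows) < 3:
        raise ValueError("need at least 3 genes shared between binding and TE tables")
    df = pd.DataFrame(rows, columns=["gene_id", "binding_ratio", "log2_dte"])
    rho, p = stats.spearmanr(df["binding_ratio"], df["log2_dte"])
    return CorrelationResult(rho=float(rho), p_value=float(p), n=len(df), table=df)
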