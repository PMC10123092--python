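"""Synthetic transcriptomes and 40S/80S footprint libraries.

The generator emulates the statistical structure selective ribosome
footprinting analyses rely on, so every downstream stage can be exercised
without sequencing data:

* a single 43S scanning stream enters each 5'UTR at the cap; at every uORF
  start codon a Kozak-dependent fraction initiates (leaving the scanning
  pool), the remainder leaky-scans onward;
* scanning 40S footprints are Poisson with mean scan_density x local
  scanning flux; elongating 80S footprints on an ORF are Poisson with mean
  elong_density x initiation flux into that ORF;
* selective-IP libraries are binomial thinnings of the matched total
  library. On designated "interactor" transcripts the 80S capture
  probability steps from ip_base_rate to ip_step_rate at a fixed fraction
  of the CDS, mimicking co-translational binding once the interacting
  domain has emerged from the ribosome;
* a "knockdown" condition multiplies every uORF initiation probability by
  depletion_leak_shift (values > 1 mean less leaky scanning, i.e. more uORF
  translation and less main-ORF initiation).

Identical seed and configuration give bit-identical output; per-transcript
RNG substreams are derived deterministically so results do not depend on
iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .tracks import (
    Interval,
    STOP_CODONS,
    FootprintTrack,
    TranscriptModel,
    UORF,
)

CONDITIONS = ("control", "knockdown")
_COND_CODE = {"control": 0, "knockdown": 1}
_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the generative model. Probabilities in [0,1], densities >= 0."""

    n_transcripts: int = 200
    utr_len_range: tuple[int, int] = (150, 300)
    cds_len_range: tuple[int, int] = (300, 900)
    utr3_len_range: tuple[int, int] = (50, 150)
    uorf_rate: float = 0.8  # Poisson mean AUG-uORFs per 5'UTR
    # zero-strength starts model bioinformatically annotated but silent uORFs
    kozak_strengths: tuple[float, ...] = (0.0, 0.1, 0.25, 0.5)
    main_init_prob: float = 0.65  # mORF start codons sit in strong context
    scan_density: float = 0.5  # expected 40S reads per nt per unit scanning flux
    elong_density: float = 16.0  # expected 80S reads per nt per unit initiation flux
    ip_base_rate: float = 0.05  # selective-IP capture probability, pre-breakpoint
    ip_step_rate: float = 0.5  # capture probability after the breakpoint
    interactor_fraction: float = 0.05
    breakpoint_frac: float = 0.4  # breakpoint position as fraction of CDS length
    depletion_leak_shift: float = 2.0  # x on uORF init prob in "knockdown"
    reinit_prob: float = 0.0  # probability of resuming scanning after a uORF
    ip_utr_base_rate: float = 0.2  # 40S selective capture, transcripts without uORFs
    ip_utr_uorf_rate: float | None = None  # 40S capture on uORF-containing transcripts
    rna_depth: float = 0.1  # expected RNA-seq reads per nt
    seed: int = 0

    def validate(self) -> None:
        for name in ("utr_len_range", "cds_len_range", "utr3_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"degenerate {name}: ({lo}, {hi})")
        probs = [self.main_init_prob, self.ip_base_rate, self.ip_step_rate,
                 self.interactor_fraction, self.breakpoint_frac, self.reinit_prob,
                 self.ip_utr_base_rate, *self.kozak_strengths]
        if self.ip_utr_uorf_rate is not None:
            probs.append(self.ip_utr_uorf_rate)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if min(self.uorf_rate, self.scan_density, self.elong_density, self.rna_depth) < 0:
            raise ValueError("rates and densities must be non-negative")
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be positive")


@dataclass
class TruthEntry:
    """Ground truth for one simulated transcript."""

    transcript_id: str
    is_interactor: bool
    breakpoint_nt: int | None  # CDS coordinates; defined iff is_interactor
    uorf_init_probs: list[float]
    intercistronic: list[int]  # uORF stop to mORF start distance, per uORF
    main_init_prob: float
    morf_flux: dict[str, float]  # condition -> initiation flux into the mORF
    ip_utr_rate: float


@dataclass
class SimTruth:
    entries: dict[str, TruthEntry] = field(default_factory=dict)

    def __getitem__(self, transcript_id: str) -> TruthEntry:
        return self.entries[transcript_id]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries.values():
            rows.append({
                "transcript_id": e.transcript_id,
                "is_interactor": e.is_interactor,
                "breakpoint_nt": -1 if e.breakpoint_nt is None else e.breakpoint_nt,
                "n_uorfs": len(e.uorf_init_probs),
                "uorf_init_probs": ",".join(f"{p:g}" for p in e.uorf_init_probs),
                "main_init_prob": e.main_init_prob,
                "morf_flux_control": e.morf_flux["control"],
                "morf_flux_knockdown": e.morf_flux["knockdown"],
                "ip_utr_rate": e.ip_utr_rate,
            })
        return pd.DataFrame(rows)


def _rng(config: SimConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, *stream])


def _scrub_stop_in_frame(seq: list[str], start: int, end: int) -> None:
    """Remove in-frame stop codons in [start, end) by a C substitution.

    Replacing any base with C can neither create a stop codon nor an ATG
    (neither contains C), so a single pass is sufficient.
    """
    for p in range(start, end - 2, 3):
        if "".join(seq[p:p + 3]) in STOP_CODONS:
            seq[p + 1] = "C"


def _simulate_one_transcript(i: int, config: SimConfig):
    rng = _rng(config, i, 0)
    utr_len = int(rng.integers(config.utr_len_range[0], config.utr_len_range[1] + 1))
    cds_len = int(rng.integers(config.cds_len_range[0], config.cds_len_range[1] + 1))
    cds_len -= cds_len % 3
    cds_len = max(cds_len, 6)
    utr3_len = int(rng.integers(config.utr3_len_range[0], config.utr3_len_range[1] + 1))
    total_len = utr_len + cds_len + utr3_len
    cds_start = utr_len
    cds_end = utr_len + cds_len

    # place AUG-uORFs: non-overlapping, left to right, stop before the mORF
    n_uorfs = int(rng.poisson(config.uorf_rate))
    uorfs: list[UORF] = []
    init_probs: list[float] = []
    cursor = 3  # leave a short cap-proximal stretch
    for _ in range(n_uorfs):
        ulen = 3 * int(rng.integers(2, 11))  # 6..30 nt including start+stop
        lo = cursor
        hi = cds_start - ulen
        if lo > hi:
            break
        s = int(rng.integers(lo, hi + 1))
        uorfs.append(UORF(start=s, stop_end=s + ulen, frame=s % 3))
        init_probs.append(float(rng.choice(config.kozak_strengths)))
        cursor = s + ulen + 1
    seq = list(_BASES[rng.integers(0, 4, size=total_len)])

    # plant the mORF: ATG ... (stop-free body) ... stop
    seq[cds_start:cds_start + 3] = list("ATG")
    seq[cds_end - 3:cds_end] = list(str(rng.choice(STOP_CODONS)))
    _scrub_stop_in_frame(seq, cds_start + 3, cds_end - 3)

    # plant uORFs and scrub premature in-frame stops within each body
    for u in uorfs:
        seq[u.start:u.start + 3] = list("ATG")
        seq[u.stop_end - 3:u.stop_end] = list(str(rng.choice(STOP_CODONS)))
        _scrub_stop_in_frame(seq, u.start + 3, u.stop_end - 3)

    # remove spurious ATGs in the 5'UTR so the annotation equals ground truth
    protected: set[int] = set()
    for u in uorfs:
        protected.update(range(u.start, u.start + 3))
        protected.update(range(u.stop_end - 3, u.stop_end))
    p = 0
    while p < cds_start - 2:
        if seq[p] == "A" and seq[p + 1] == "T" and seq[p + 2] == "G" and not any(
                u.start == p for u in uorfs):
            for q in (p, p + 1, p + 2):
                if q not in protected:
                    seq[q] = "C"
                    break
        p += 1

    model = TranscriptModel(
        transcript_id=f"TX{i:05d}",
        utr5=Interval(0, cds_start),
        cds=Interval(cds_start, cds_end),
        utr3=Interval(cds_end, total_len),
        sequence="".join(seq),
        uorfs=uorfs,
    )
    is_interactor = bool(rng.random() < config.interactor_fraction)
    breakpoint_nt = int(round(config.breakpoint_frac * cds_len)) if is_interactor else None
    # factor-like capture follows actively translated uORFs, not silent ones
    if config.ip_utr_uorf_rate is not None and any(p > 0 for p in init_probs):
        ip_utr = config.ip_utr_uorf_rate
    else:
        ip_utr = config.ip_utr_base_rate
    morf_flux = {
        cond: _scanning_flux(model, init_probs, config, cond)[1]
        for cond in CONDITIONS
    }  # analytic per-condition flux, for truth bookkeeping
    entry = TruthEntry(
        transcript_id=model.transcript_id,
        is_interactor=is_interactor,
        breakpoint_nt=breakpoint_nt,
        uorf_init_probs=init_probs,
        intercistronic=[cds_start - u.stop_end for u in uorfs],
        main_init_prob=config.main_init_prob,
        morf_flux=morf_flux,
        ip_utr_rate=float(ip_utr),
    )
    return model, entry


def simulate_transcriptome(config: SimConfig) -> tuple[list[TranscriptModel], SimTruth]:
    """Draw a transcriptome and its ground truth from the generative model."""
    config.validate()
    models: list[TranscriptModel] = []
    truth = SimTruth()
    for i in range(config.n_transcripts):
        model, entry = _simulate_one_transcript(i, config)
        model.validate()
        models.append(model)
        truth.entries[model.transcript_id] = entry
    return models, truth


def _uorf_init_prob(p: float, config: SimConfig, condition: str) -> float:
    if condition == "knockdown":
        return min(1.0, p * config.depletion_leak_shift)
    return p


def _scanning_flux(transcript: TranscriptModel, init_probs: Sequence[float],
                   config: SimConfig, condition: str
                   ) -> tuple[np.ndarray, float, dict[int, float]]:
    """Scanning flux along the 5'UTR, the mORF initiation flux, and the
    per-uORF initiation fluxes keyed by uORF start.

    One unit of 43S flux enters at the cap; a per-uORF fraction initiates
    at each start codon and (optionally) a fraction of terminating uORF
    ribosomes resumes scanning downstream of the uORF stop.
    """
    cds_start = transcript.cds.start
    flux = np.empty(cds_start, dtype=float)
    running = 1.0
    pointer = 0
    uorf_flux: dict[int, float] = {}
    reinit_gains: list[tuple[int, float]] = []
    for u, p in zip(transcript.uorfs, init_probs):
        p_eff = _uorf_init_prob(p, config, condition)
        flux[pointer:u.start] = running
        initiated = running * p_eff
        uorf_flux[u.start] = initiated
        running -= initiated
        pointer = u.start
        if config.reinit_prob > 0 and u.stop_end <= cds_start:
            reinit_gains.append((u.stop_end, initiated * config.reinit_prob))
    flux[pointer:cds_start] = running
    for pos, gain in reinit_gains:
        flux[pos:cds_start] += gain
    morf_flux = (flux[cds_start - 1] if cds_start > 0 else 1.0) * config.main_init_prob
    return flux, float(morf_flux), uorf_flux


def simulate_footprints(transcripts: Sequence[TranscriptModel], truth: SimTruth,
                        condition: str, config: SimConfig) -> dict[str, FootprintTrack]:
    """Simulate the four libraries of one condition.

    Returns tracks keyed ``total_40s``, ``selective_40s``, ``total_80s``,
    ``selective_80s``.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    cond_code = _COND_CODE[condition]
    counts = {key: {} for key in ("total_40s", "selective_40s", "total_80s", "selective_80s")}
    for i, t in enumerate(transcripts):
        entry = truth[t.transcript_id]
        rng = _rng(config, i, cond_code, 1)
        n = t.length
        cds_start, cds_end = t.cds

        # ---- 40S: scanning density over the 5'UTR
        flux, morf_flux, uorf_flux = _scanning_flux(t, entry.uorf_init_probs, config, condition)
        mean40 = np.zeros(n, dtype=float)
        mean40[:cds_start] = config.scan_density * flux
        total40 = rng.poisson(mean40)
        sel40 = rng.binomial(total40, entry.ip_utr_rate)

        # ---- 80S: elongating density on uORFs and the mORF
        mean80 = np.zeros(n, dtype=float)
        for u in t.uorfs:
            mean80[u.start:u.stop_end] += config.elong_density * uorf_flux.get(u.start, 0.0)
        mean80[cds_start:cds_end] += config.elong_density * morf_flux
        total80 = rng.poisson(mean80)
        p80 = np.full(n, config.ip_base_rate, dtype=float)
        if entry.is_interactor and entry.breakpoint_nt is not None:
            p80[cds_start + entry.breakpoint_nt:] = config.ip_step_rate
        sel80 = rng.binomial(total80, p80)

        counts["total_40s"][t.transcript_id] = total40
        counts["selective_40s"][t.transcript_id] = sel40
        counts["total_80s"][t.transcript_id] = total80
        counts["selective_80s"][t.transcript_id] = sel80

    def mk(key: str, species: str, mode: str) -> FootprintTrack:
        return FootprintTrack(library_id=f"{condition}_{key}", species=species,
                              mode=mode, counts=counts[key])

    return {
        "total_40s": mk("total_40s", "40S", "total"),
        "selective_40s": mk("selective_40s", "40S", "selective"),
        "total_80s": mk("total_80s", "80S", "total"),
        "selective_80s": mk("selective_80s", "80S", "selective"),
    }


def simulate_rna_counts(transcripts: Sequence[TranscriptModel], condition: str,
                        config: SimConfig) -> dict[str, int]:
    """Poisson RNA-seq gene counts; expression is unchanged between conditions."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    out = {}
    for i, t in enumerate(transcripts):
        rng = _rng(config, i, _COND_CODE[condition], 2)
        out[t.transcript_id] = int(rng.poisson(config.rna_depth * t.length))
    return out


def write_truth_tsv(truth: SimTruth, path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def config_from_dict(d: dict) -> SimConfig:
    known = {f for f in SimConfig.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
    d = dict(d)
    for key in ("utr_len_range", "cds_len_range", "utr3_len_range", "kozak_strengths"):
        if key in d:
            d[key] = tuple(d[key])
    return SimConfig(**d)
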