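"""End-to-end pipeline: simulate/load -> score -> uORFs -> metagene -> selectivity.

A run is described by a single YAML config with per-stage blocks and is
fully reproducible: the manifest records the package version, a hash of
the resolved config, the seed, and a SHA-256 checksum of every output
file, so identical config+seed runs produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import assembly, metagene, selectivity, synthetic, tracks, uorfs

ALL_STAGES = ("simulate", "score", "uorf", "metagene", "selectivity", "te")


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    simulate: dict | None = None  # SimConfig block
    inputs: dict | None = None  # paths: annotation, sequences, tracks, rna_counts
    score: dict = field(default_factory=dict)
    uorf: dict = field(default_factory=dict)
    metagene: dict = field(default_factory=dict)
    selectivity: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        raw["outdir"] = Path(raw.get("outdir", "riboselect_run"))
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config must supply exactly one of 'simulate' or 'inputs'")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.inputs is not None:
            if "simulate" in self.stages:
                raise ValueError("'simulate' stage requires a 'simulate' config block")
            for key, p in self.inputs.items():
                if isinstance(p, (str, Path)) and not Path(p).exists():
                    raise ValueError(f"input {key!r}: file not found: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; return the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "riboselect",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(_jsonable(config), sort_keys=True).encode()).hexdigest(),
        "stages": {},
    }
    state: dict = {}
    stage = None
    try:
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            t0 = time.perf_counter()
            outputs, n_records = _STAGE_FUNCS[stage](config, state, outdir)
            manifest["stages"][stage] = {
                "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
                "n_records": n_records,
                "seconds": round(time.perf_counter() - t0, 3),
            }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _jsonable(config: RunConfig) -> dict:
    d = {k: getattr(config, k) for k in config.__dataclass_fields__}
    d["outdir"] = str(d["outdir"])
    return d


def _ensure_data(config: RunConfig, state: dict) -> None:
    """Load or simulate transcripts + tracks into the shared state."""
    if "transcripts" in state:
        return
    if config.simulate is not None:
        sim = dict(config.simulate)
        sim.setdefault("seed", config.seed)
        sc = synthetic.config_from_dict(sim)
        transcripts, truth = synthetic.simulate_transcriptome(sc)
        state["sim_config"] = sc
        state["truth"] = truth
        state["transcripts"] = transcripts
        state["tracks"] = {cond: synthetic.simulate_footprints(transcripts, truth, cond, sc)
                           for cond in synthetic.CONDITIONS}
        state["rna"] = {cond: synthetic.simulate_rna_counts(transcripts, cond, sc)
                        for cond in synthetic.CONDITIONS}
    else:
        inputs = config.inputs or {}
        seqs = tracks.read_sequences_fasta(inputs["sequences"]) if "sequences" in inputs else None
        transcripts = tracks.read_annotation(inputs["annotation"], sequences=seqs)
        state["transcripts"] = transcripts
        loaded: dict = {"control": {}}
        for key, path in (inputs.get("tracks") or {}).items():
            species = "40S" if "40s" in key else "80S"
            mode = "selective" if "selective" in key else "total"
            loaded["control"][key] = tracks.read_track(path, transcripts, species, mode,
                                                       library_id=key)
        state["tracks"] = loaded
        if "rna_counts" in inputs:
            df = pd.read_csv(inputs["rna_counts"], sep="\t")
            state["rna"] = {c: dict(zip(df["gene_id"], df[c]))
                            for c in df.columns if c != "gene_id"}


def _stage_simulate(config: RunConfig, state: dict, outdir: Path):
    _ensure_data(config, state)
    transcripts = state["transcripts"]
    paths = []
    p = outdir / "annotation.gff3"
    tracks.write_annotation_gff3(transcripts, p)
    paths.append(p)
    p = outdir / "sequences.fa"
    tracks.write_sequences_fasta(transcripts, p)
    paths.append(p)
    if "truth" in state:
        p = outdir / "truth.tsv"
        synthetic.write_truth_tsv(state["truth"], p)
        paths.append(p)
    for cond, libs in state["tracks"].items():
        for key, tr in libs.items():
            p = outdir / f"{cond}_{key}.bedgraph"
            tracks.write_track_bedgraph(tr, p)
            paths.append(p)
    if "rna" in state:
        rna = state["rna"]
        conds = list(rna)
        genes = sorted(rna[conds[0]])
        df = pd.DataFrame({"gene_id": genes,
                           **{c: [rna[c][g] for g in genes] for c in conds}})
        p = outdir / "rna_counts.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths.append(p)
    return paths, len(transcripts)


def _stage_score(config: RunConfig, state: dict, outdir: Path):
    _ensure_data(config, state)
    libs = state["tracks"]["control"]
    table = assembly.score_all_genes(
        libs["selective_80s"], libs["total_80s"], state["transcripts"],
        **config.score)
    p = outdir / "assembly_scores.tsv"
    table.to_csv(p, sep="\t", index=False, float_format="%.6g")
    return [p], len(table)


def _stage_uorf(config: RunConfig, state: dict, outdir: Path):
    _ensure_data(config, state)
    transcripts = state["transcripts"]
    uorfs.annotate_uorfs(transcripts,
                         allow_near_cognate=config.uorf.get("allow_near_cognate", False))
    total80 = state["tracks"]["control"]["total_80s"]
    cats = uorfs.categorize_transcripts(
        transcripts, total80, min_reads=config.uorf.get("min_uorf_reads", 1))
    rows = [{"transcript_id": t.transcript_id,
             "n_uorfs": len(t.uorfs),
             "n_translated": sum(1 for u in t.uorfs if u.translated),
             "category": cats[t.transcript_id]} for t in transcripts]
    p = outdir / "uorfs.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    state["categories"] = cats
    return [p], len(rows)


def _stage_metagene(config: RunConfig, state: dict, outdir: Path):
    _ensure_data(config, state)
    window = tuple(config.metagene.get("window", (-100, 200)))
    smooth_w = config.metagene.get("smooth", 3)
    anchor = config.metagene.get("anchor", "uorf_start")
    scan_window = tuple(config.metagene.get("scan_window", (-100, -80)))
    conds = list(state["tracks"])
    # collect per-library profiles across conditions, then normalize jointly:
    # 80S by library depth, 40S by equalized upstream scanning signal
    profiles: dict[str, dict[str, metagene.MetageneProfile]] = {"total_80s": {}, "total_40s": {}}
    for cond in conds:
        libs = state["tracks"][cond]
        kwargs = {}
        if anchor.startswith("uorf"):
            kwargs["uorf_filter_track"] = libs["total_80s"]
        for key in profiles:
            profiles[key][cond] = metagene.metagene_profile(
                libs[key], state["transcripts"], anchor, window=window, **kwargs)
    profiles["total_80s"] = metagene.normalize_80s(
        profiles["total_80s"],
        {c: state["tracks"][c]["total_80s"].library_size for c in conds})
    if scan_window[0] >= window[0] and scan_window[1] <= window[1] and \
            anchor in ("morf_start", "uorf_start"):
        profiles["total_40s"] = metagene.normalize_scanning(profiles["total_40s"],
                                                            scan_window=scan_window)
    else:
        profiles["total_40s"] = metagene.normalize_80s(
            profiles["total_40s"],
            {c: state["tracks"][c]["total_40s"].library_size for c in conds})
    paths = []
    frames = []
    for key, by_cond in profiles.items():
        for cond, prof in by_cond.items():
            sm = metagene.smooth_profile(prof, smooth_w)
            frames.append(pd.DataFrame({
                "condition": cond, "library": key, "offset": prof.offsets,
                "raw": prof.values, "smoothed": sm.values, "n": prof.n_per_offset,
            }))
    p = outdir / f"metagene_{anchor}.tsv"
    pd.concat(frames).to_csv(p, sep="\t", index=False, float_format="%.6g")
    paths.append(p)
    return paths, sum(len(f) for f in frames)


def _stage_selectivity(config: RunConfig, state: dict, outdir: Path):
    _ensure_data(config, state)
    libs = state["tracks"]["control"]
    stats_list = selectivity.binding_ratio_per_gene(
        libs["selective_40s"], libs["total_40s"], state["transcripts"],
        pseudocount=config.selectivity.get("pseudocount", 0.5))
    table = selectivity.decile_groups(stats_list,
                                      fraction=config.selectivity.get("fraction", 0.1))
    p = outdir / "binding_ratios.tsv"
    table.to_csv(p, sep="\t", index=False, float_format="%.6g")
    state["binding"] = stats_list
    paths = [p]
    if "categories" in state:
        comp = selectivity.compare_binding_by_uorf_category(stats_list, state["categories"])
        p2 = outdir / "binding_by_category.json"
        p2.write_text(json.dumps({
            "group_sizes": comp.group_sizes,
            "group_medians": comp.group_medians,
            "kruskal_H": comp.statistic,
            "kruskal_p": comp.p_value,
            "pairwise": comp.pairwise.to_dict(orient="records"),
        }, indent=2))
        paths.append(p2)
    return paths, len(stats_list)


def _stage_te(config: RunConfig, state: dict, outdir: Path):
    _ensure_data(config, state)
    if "rna" not in state or "knockdown" not in state["tracks"]:
        raise ValueError("TE stage needs RNA counts and both conditions")
    te = selectivity.translation_efficiency(
        {c: state["tracks"][c]["total_80s"] for c in ("control", "knockdown")},
        state["rna"], state["transcripts"])
    df = pd.DataFrame([{"gene_id": r.gene_id, "te_control": r.te_control,
                        "te_treated": r.te_treated, "log2_dte": r.log2_dte}
                       for r in te])
    p = outdir / "translation_efficiency.tsv"
    df.to_csv(p, sep="\t", index=False, float_format="%.6g")
    paths = [p]
    if "binding" in state:
        corr = selectivity.correlate_binding_vs_dte(state["binding"], te)
        p2 = outdir / "binding_vs_dte.json"
        p2.write_text(json.dumps({"rho": corr.rho, "p_value": corr.p_value,
                                  "n": corr.n}, indent=2))
        paths.append(p2)
    return paths, len(df)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "score": _stage_score,
    "uorf": _stage_uorf,
    "metagene": _stage_metagene,
    "selectivity": _stage_selectivity,
    "te": _stage_te,
}
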