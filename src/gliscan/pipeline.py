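"""Stage orchestration: run the analysis end to end with manifests.

Stages mirror the workflow order (synth -> library -> train -> scan ->
evaluate -> profile -> gko). Each stage writes its artifacts into the
configured output directory together with a JSON manifest recording
input-file hashes, parameters and the seed, so every numeric output is
traceable. Stages check for their upstream artifacts and fail with an
error naming the missing prior stage.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import evaluate as ev
from . import motifs, scan, simulate, svm
from .core import Genome, Region, read_bed, read_fasta, write_bed

STAGES = ("synth", "library", "train", "scan", "evaluate", "profile", "gko")


@dataclass
class RunConfig:
    outdir: str = "results/run"
    seed: int = 0
    # synth
    n_pos: int = 1000
    genome_length: int = 4_000_000
    gc: float = 0.42
    p_single_gbm: float = 0.88
    # library
    library_alpha: float = 0.05
    # train
    k: int = 8
    C: float = 1.0
    n_repeats: int = 5
    train_frac: float = 0.8
    gc_tol: float = 0.02
    # scan
    window_width: int = 600
    # evaluate
    track_p_enh: float = 0.8
    track_p_bg: float = 0.3
    track_n_bg: int = 50

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, config: RunConfig,
                    inputs: list[Path], started: float) -> None:
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "parameters": asdict(config),
        "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
        "elapsed_s": round(time.time() - started, 3),
    }
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def _require(outdir: Path, filename: str, prior_stage: str) -> Path:
    p = outdir / filename
    if not p.exists():
        raise FileNotFoundError(
            f"missing artifact {filename!r}: run stage {prior_stage!r} first"
        )
    return p


def run_stage(stage: str, config: RunConfig) -> dict:
    """Run one pipeline stage; returns a small summary dict."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; valid: {STAGES}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = time.time()
    summary = _STAGE_FNS[stage](config, outdir)
    _write_manifest(outdir, stage, config, summary.pop("_inputs", []), started)
    return summary


def _stage_synth(config: RunConfig, outdir: Path) -> dict:
    grammar = simulate.GrammarConfig(
        p_single_gbm=config.p_single_gbm, gc=config.gc
    )
    # decoy sites give the scan stage non-enhancer GBM windows, so the
    # evaluate stage has predicted negatives to compare against
    study = simulate.default_study(
        n_pos=config.n_pos,
        genome_length=config.genome_length,
        grammar=grammar,
        seed=config.seed,
        n_decoy_gbm=config.n_pos,
    )
    study.write(outdir)
    return {"n_peaks": config.n_pos, "genome_length": config.genome_length,
            "_inputs": []}


def _stage_library(config: RunConfig, outdir: Path) -> dict:
    genome_fa = _require(outdir, "genome.fa", "synth")
    peaks_bed = _require(outdir, "peaks_SYN.bed", "synth")
    genome = read_fasta(genome_fa)
    peaks = read_bed(peaks_bed)
    seqs = [genome.fetch(r.contig, r.start, r.end) for r in peaks]
    lib = motifs.iterative_library_build(
        {"SYN": seqs}, alpha=config.library_alpha, rng_seed=config.seed
    )
    lib.to_tsv(outdir / "library.tsv")
    return {"n_motifs": len(lib), "_inputs": [genome_fa, peaks_bed]}


def _load_training_sets(config: RunConfig, outdir: Path):
    genome = read_fasta(_require(outdir, "genome.fa", "synth"))
    peaks = read_bed(_require(outdir, "peaks_SYN.bed", "synth"))
    lib = motifs.MotifLibrary.from_tsv(_require(outdir, "library.tsv", "library"))
    seqs = [genome.fetch(r.contig, r.start, r.end) for r in peaks]
    # wGBM restriction: keep peaks containing >= 1 library site
    keep = [i for i, s in enumerate(seqs)
            if any(w in s or motifs.revcomp(w) in s for w in lib.words)]
    pos_regions = [peaks[i] for i in keep]
    pos_seqs = [seqs[i] for i in keep]
    bg = scan.sample_gc_matched_background(
        genome, pos_regions, gc_tol=config.gc_tol, seed=config.seed + 11
    )
    return genome, lib, pos_regions, pos_seqs, bg


def _stage_train(config: RunConfig, outdir: Path) -> dict:
    genome, lib, pos_regions, pos_seqs, bg = _load_training_sets(config, outdir)
    curves = svm.evaluate_repeated_holdout(
        pos_seqs, bg.sequences,
        n_repeats=config.n_repeats, train_frac=config.train_frac,
        seed=config.seed, k=config.k, C=config.C,
    )
    curves.to_csv(outdir / "curves_SYN.csv")
    model = svm.train(pos_seqs, bg.sequences, k=config.k, C=config.C,
                      seed=config.seed)
    model.to_tsv(outdir / "model_SYN.tsv")
    write_bed(bg.regions, outdir / "background_SYN.bed")
    return {
        "n_pos": len(pos_seqs), "n_neg": len(bg.sequences),
        "mean_roc_auc": curves.mean_roc_auc,
        "mean_prc_auc": curves.mean_prc_auc,
        "_inputs": [outdir / "genome.fa", outdir / "peaks_SYN.bed",
                    outdir / "library.tsv"],
    }


def _stage_scan(config: RunConfig, outdir: Path) -> dict:
    genome = read_fasta(_require(outdir, "genome.fa", "synth"))
    lib = motifs.MotifLibrary.from_tsv(_require(outdir, "library.tsv", "library"))
    model_path = _require(outdir, "model_SYN.tsv", "train")
    model = svm.KmerModel.from_tsv(model_path)
    scored = scan.scan_and_score(genome, lib, {"SYN": model},
                                 width=config.window_width)
    with open(outdir / "scored_windows.tsv", "w") as fh:
        fh.write("contig\tstart\tend\tword\tscore\tposterior\tcall\n")
        for w in scored:
            fh.write(
                f"{w.region.contig}\t{w.region.start}\t{w.region.end}\t"
                f"{w.gbm.word}\t{w.scores['SYN']:.6g}\t"
                f"{w.posteriors['SYN']:.6g}\t{int(w.calls['SYN'])}\n"
            )
    n_positive = sum(w.calls["SYN"] for w in scored)
    return {"n_windows": len(scored), "n_positive_calls": int(n_positive),
            "_inputs": [outdir / "genome.fa", outdir / "library.tsv",
                        model_path]}


def _read_scored(outdir: Path) -> list[tuple[Region, float, float, bool]]:
    rows = []
    with open(_require(outdir, "scored_windows.tsv", "scan")) as fh:
        fh.readline()
        for line in fh:
            c, s, e, word, sc, post, call = line.rstrip("\n").split("\t")
            rows.append((Region(c, int(s), int(e), label=word),
                         float(sc), float(post), call == "1"))
    return rows


def _stage_evaluate(config: RunConfig, outdir: Path) -> dict:
    genome = read_fasta(_require(outdir, "genome.fa", "synth"))
    truth = read_bed(_require(outdir, "truth_regions.bed", "synth"))
    scored = _read_scored(outdir)
    pos = [r for r, sc, _, call in scored if call]
    neg = [r for r, sc, _, call in scored if not call]
    bg_path = outdir / "background_SYN.bed"
    bg_regions = read_bed(bg_path) if bg_path.exists() else None
    track = simulate.generate_feature_track(
        truth, config.track_p_enh, config.track_p_bg, config.track_n_bg,
        seed=config.seed + 23, genome=genome,
        background_regions=bg_regions, name="synthetic_dnase",
    )
    write_bed(track.regions, outdir / "track_synthetic_dnase.bed")
    stats = ev.overlap_ztest(pos, neg, track)
    rows = ev.ztest_report_rows({"synthetic_dnase": stats})
    with open(outdir / "ztest_report.tsv", "w") as fh:
        cols = list(rows[0])
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    return {"z": stats.z, "p_value": stats.p_value,
            "n_pos": len(pos), "n_neg": len(neg),
            "_inputs": [outdir / "scored_windows.tsv",
                        outdir / "truth_regions.bed"]}


def _stage_profile(config: RunConfig, outdir: Path) -> dict:
    genome = read_fasta(_require(outdir, "genome.fa", "synth"))
    model = svm.KmerModel.from_tsv(_require(outdir, "model_SYN.tsv", "train"))
    scored = _read_scored(outdir)
    if not scored:
        raise RuntimeError("no scored windows to profile")
    best = max(scored, key=lambda t: t[1])
    region = best[0]
    seq = genome.fetch(region.contig, region.start, region.end)
    profile = scan.weight_profile(model, seq)
    scan.profile_to_bedgraph(profile, region.contig, region.start,
                             outdir / "profile_top_window.bedgraph")
    return {"top_window": f"{region.contig}:{region.start}-{region.end}",
            "top_score": best[1], "profile_sum": float(profile.sum()),
            "_inputs": [outdir / "scored_windows.tsv",
                        outdir / "model_SYN.tsv"]}


def _stage_gko(config: RunConfig, outdir: Path) -> dict:
    genome = read_fasta(_require(outdir, "genome.fa", "synth"))
    lib = motifs.MotifLibrary.from_tsv(_require(outdir, "library.tsv", "library"))
    model = svm.KmerModel.from_tsv(_require(outdir, "model_SYN.tsv", "train"))
    scored = _read_scored(outdir)
    if not scored:
        raise RuntimeError("no scored windows for GKO")
    best = max(scored, key=lambda t: t[1])
    region = best[0]
    seq = genome.fetch(region.contig, region.start, region.end)
    sub = Genome({"w": seq})
    matches = motifs.scan_genome_for_gbm(sub, lib)
    mutated = motifs.gko_mutate(seq, matches)
    wt_score = svm.score(model, seq)
    gko_score = svm.score(model, mutated)
    with open(outdir / "gko_report.tsv", "w") as fh:
        fh.write("window\tn_sites\twt_score\tgko_score\tdelta\n")
        fh.write(f"{region.contig}:{region.start}-{region.end}\t{len(matches)}\t"
                 f"{wt_score:.6g}\t{gko_score:.6g}\t{gko_score - wt_score:.6g}\n")
    return {"n_sites": len(matches), "wt_score": wt_score,
            "gko_score": gko_score,
            "_inputs": [outdir / "scored_windows.tsv",
                        outdir / "model_SYN.tsv", outdir / "library.tsv"]}


_STAGE_FNS = {
    "synth": _stage_synth,
    "library": _stage_library,
    "train": _stage_train,
    "scan": _stage_scan,
    "evaluate": _stage_evaluate,
    "profile": _stage_profile,
    "gko": _stage_gko,
}
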