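"""Configuration-driven orchestration of the integrant analysis stages.

Stages run in dependency order::

    simulate -> annotate -> classify -> count -> de -> enrich -> patterns

``simulate`` writes synthetic upstream inputs (RepeatMasker .out, pairing
table, chromosome sizes) when real ones are not supplied; downstream stages
consume either those or user-provided files.  Every run writes a manifest
recording input hashes, parameters and seeds; deterministic stages reproduce
byte-identical outputs under the same configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expression import call_de, moderated_t_test, normalize_logcpm
from .intervals import (
    GenomicInterval,
    OverlapMode,
    classify_features,
    distance_to_nearest,
    genome_coverage_fraction,
    read_bed,
)
from .medip import (
    enrichment_change,
    expression_hydroxymethylation_correlation,
    ip_over_input,
    rrbs_feature_q75,
    subsampled_ttest,
)
from .patterns import (
    assign_patterns,
    enumerate_patterns,
    family_enrichment,
    fit_gg_em,
    min_reads_filter,
    preset_patterns,
)
from .quantify import CountMatrix, low_count_filter
from .repeats import (
    merge_integrants,
    parse_repeatmasker_out,
    read_pairing_table,
    write_integrants_bed,
    write_repeatmasker_out,
)
from .simulate import (
    SimConfig,
    rng_for,
    simulate_counts,
    simulate_ip_input,
    simulate_repeat_hits,
    simulate_rrbs_and_peaks,
)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "annotate", "classify", "count", "de", "enrich", "patterns")

_STAGE_DEPS = {
    "simulate": (),
    "annotate": ("simulate",),
    "classify": ("annotate",),
    "count": ("annotate",),
    "de": ("count",),
    "enrich": ("de",),
    "patterns": ("count",),
}

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Resolved pipeline parameters; unknown keys are rejected at load time."""

    output_dir: str = "tekit_out"
    seed: int = 0
    max_gap: int = 400
    overlap_fraction: float = 0.25
    fc_threshold: float = 2.0
    alpha: float = 0.05
    min_reads: int = 20
    pattern_space: str = "preset"  # preset | all
    de_contrast: list = field(default_factory=lambda: ["WT.ctrl", "WT.kd"])
    n_genes: int = 400
    inputs: dict = field(default_factory=dict)  # optional real input paths
    sim: dict = field(default_factory=dict)  # SimConfig overrides

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if not (0 < self.overlap_fraction <= 1):
            raise ValueError("overlap_fraction must be in (0, 1]")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.pattern_space not in ("preset", "all"):
            raise ValueError("pattern_space must be 'preset' or 'all'")
        known_sim = {f.name for f in fields(SimConfig)}
        unknown = set(self.sim) - known_sim
        if unknown:
            raise ValueError(f"unknown sim keys: {sorted(unknown)}")

    def sim_config(self) -> SimConfig:
        sim = dict(self.sim)
        sim.setdefault("seed", self.seed)
        return SimConfig(**sim)

    def to_dict(self) -> dict:
        return asdict(self)


def validate_config(path_or_dict) -> PipelineConfig:
    """Load and validate a YAML config file (or a dict); unknown keys error."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict or {})
    known = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
    for path in (raw.get("inputs") or {}).values():
        if not Path(path).exists():
            raise FileNotFoundError(f"configured input does not exist: {path}")
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(outdir: Path, stage: str, *names: str) -> None:
    for name in names:
        if not (outdir / name).exists():
            raise FileNotFoundError(
                f"stage {stage!r} needs {name!r}; run its upstream stage first"
            )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    sim = cfg.sim_config()
    hits, pairing, truth = simulate_repeat_hits(sim)
    with open(outdir / "repeats.out", "w") as fh:
        write_repeatmasker_out(hits, fh)
    with open(outdir / "pairing.tsv", "w") as fh:
        for internal, ltrs in sorted(pairing.items()):
            for ltr in sorted(ltrs):
                fh.write(f"{internal}\t{ltr}\n")
    with open(outdir / "chrom.sizes", "w") as fh:
        for chrom, size in sim.genome.items():
            fh.write(f"{chrom}\t{size}\n")
    _write_tsv(truth.hit_membership, outdir / "truth_hit_membership.tsv")
    _write_tsv(truth.integrants, outdir / "truth_integrants.tsv")


def _stage_annotate(cfg: PipelineConfig, outdir: Path) -> None:
    rm_path = Path(cfg.inputs.get("repeatmasker_out", outdir / "repeats.out"))
    if not rm_path.exists():
        raise FileNotFoundError("stage 'annotate' needs a RepeatMasker .out; run 'simulate' or configure inputs.repeatmasker_out")
    with open(rm_path) as fh:
        hits = parse_repeatmasker_out(fh)
    pairing = None
    pairing_path = Path(cfg.inputs.get("pairing_table", outdir / "pairing.tsv"))
    if pairing_path.exists():
        with open(pairing_path) as fh:
            pairing = read_pairing_table(fh)
    integrants = merge_integrants(hits, max_gap=cfg.max_gap, pairing=pairing)
    with open(outdir / "integrants.bed", "w") as fh:
        write_integrants_bed(integrants, fh)
    fam = pd.DataFrame(
        {"family": [t.family_name for t in integrants],
         "strand": [t.strand for t in integrants],
         "length": [t.length for t in integrants]},
        index=pd.Index([t.integrant_id for t in integrants], name="feature_id"),
    )
    _write_tsv(fam, outdir / "families.tsv")


def _integrant_intervals(outdir: Path) -> list[GenomicInterval]:
    out = []
    with open(outdir / "integrants.bed") as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            name = f[3].partition(":")[2]
            out.append(GenomicInterval(chrom=f[0], start=int(f[1]), end=int(f[2]), name=name, strand=f[5]))
    return out


def _bound_flags(cfg: PipelineConfig, ids: list[str]) -> pd.Series:
    sim = cfg.sim_config()
    rng = rng_for(sim.seed, "bound_flags")
    return pd.Series(rng.random(len(ids)) < sim.bound_fraction, index=ids, name="bound")


def _stage_classify(cfg: PipelineConfig, outdir: Path) -> None:
    _require(outdir, "classify", "integrants.bed")
    sim = cfg.sim_config()
    feats = _integrant_intervals(outdir)
    ids = [f.name for f in feats]
    if "kap1_peaks" in cfg.inputs:
        with open(cfg.inputs["kap1_peaks"]) as fh:
            peaks = {"kap1": read_bed(fh)}
        cpgs = None
    else:
        from .repeats import read_integrants_bed

        with open(outdir / "integrants.bed") as fh:
            integrants = read_integrants_bed(fh)
        bound = _bound_flags(cfg, ids)
        cpgs, peaks, _ = simulate_rrbs_and_peaks(sim, integrants, bound)
        cpgs.to_csv(outdir / "cpgs.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        with open(outdir / "peaks_kap1.bed", "w") as fh:
            for p in peaks["kap1"]:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\n")
    flags = classify_features(
        feats, peaks, {"kap1": OverlapMode("reciprocal", cfg.overlap_fraction)}
    )
    _write_tsv(flags.astype(int), outdir / "occupancy.tsv")
    sizes_path = Path(cfg.inputs.get("chrom_sizes", outdir / "chrom.sizes"))
    summary = {}
    if sizes_path.exists():
        from .intervals import read_chrom_sizes

        with open(sizes_path) as fh:
            sizes = read_chrom_sizes(fh)
        summary["kap1_genome_coverage_fraction"] = genome_coverage_fraction(peaks["kap1"], sizes)
    dists = distance_to_nearest(feats, peaks["kap1"])
    _write_tsv(dists.to_frame(), outdir / "distance_to_kap1.tsv")
    if cpgs is not None:
        q75 = rrbs_feature_q75(cpgs, feats)
        _write_tsv(q75.table, outdir / "rrbs_q75.tsv")
    (outdir / "classify_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))


def _stage_count(cfg: PipelineConfig, outdir: Path) -> None:
    _require(outdir, "count", "integrants.bed")
    sim = cfg.sim_config()
    ids = [f.name for f in _integrant_intervals(outdir)]
    if "te_counts" in cfg.inputs:
        te = CountMatrix.from_tsv(cfg.inputs["te_counts"])
        genes = CountMatrix.from_tsv(cfg.inputs["gene_counts"])
        te_truth = None
    else:
        te, te_truth = simulate_counts(sim, ids, rng_purpose="te_counts")
        gene_ids = [f"GENE{i + 1:05d}" for i in range(cfg.n_genes)]
        genes, _ = simulate_counts(sim, gene_ids, rng_purpose="gene_counts")
    genes_f = low_count_filter(genes)
    te_f = low_count_filter(te)
    gene_libs = genes_f.counts.sum(axis=0).astype(int)  # gene library sizes, voom-style
    te_f = CountMatrix(counts=te_f.counts, lib_sizes=gene_libs)
    te_f.to_tsv(outdir / "te_counts.tsv")
    genes_f.to_tsv(outdir / "gene_counts.tsv")
    if te_truth is not None:
        _write_tsv(te_truth.to_frame(), outdir / "truth_te_patterns.tsv")


def _stage_de(cfg: PipelineConfig, outdir: Path) -> None:
    _require(outdir, "de", "te_counts.tsv", "gene_counts.tsv")
    te = CountMatrix.from_tsv(outdir / "te_counts.tsv")
    g1, g2 = cfg.de_contrast
    cols = [c for c in te.sample_ids if c.rsplit(".r", 1)[0] in (g1, g2)]
    if not cols:
        raise ValueError(f"de_contrast {cfg.de_contrast} matches no sample columns")
    sub = CountMatrix(counts=te.counts[cols], lib_sizes=te.lib_sizes[cols])
    expr = normalize_logcpm(sub)
    # label Series preserves column order, so group 1 of the contrast is the baseline
    labels = pd.Series({c: c.rsplit(".r", 1)[0] for c in cols})
    result = call_de(moderated_t_test(expr, labels), fc_threshold=cfg.fc_threshold, alpha=cfg.alpha)
    _write_tsv(result.table, outdir / "de_te.tsv")
    (outdir / "de_summary.json").write_text(json.dumps(
        {"d0": result.d0, "s0_sq": result.s0_sq,
         "n_up": int((result.table["call"] == "up").sum()),
         "n_down": int((result.table["call"] == "down").sum())},
        indent=2, sort_keys=True))


def _stage_enrich(cfg: PipelineConfig, outdir: Path) -> None:
    _require(outdir, "enrich", "de_te.tsv", "te_counts.tsv")
    sim = cfg.sim_config()
    te = CountMatrix.from_tsv(outdir / "te_counts.tsv")
    ids = list(te.counts.index)
    bound = _bound_flags(cfg, [f.name for f in _integrant_intervals(outdir)]).loc[ids]
    mats, truth = simulate_ip_input(sim, ids, bound=bound)
    enr = {cond: ip_over_input(mats[(cond, "ip")], mats[(cond, "input")], condition=cond)
           for cond in ("ctrl", "kd")}
    delta = enrichment_change(enr["kd"], enr["ctrl"])
    table = pd.DataFrame({
        "log2_enr_ctrl": enr["ctrl"].log2_ip_over_input,
        "log2_enr_kd": enr["kd"].log2_ip_over_input,
        "delta": delta,
        "bound": bound.astype(int),
    })
    _write_tsv(table, outdir / "enrichment.tsv")
    p = subsampled_ttest(delta[bound].to_numpy(), delta[~bound].to_numpy(), seed=sim.seed)
    de = pd.read_csv(outdir / "de_te.tsv", sep="\t", index_col=0)
    corr = expression_hydroxymethylation_correlation(de["log2FC"], delta, bound)
    summary = {"bound_vs_unbound_p": p,
               "median_delta_bound": float(delta[bound].median()),
               "median_delta_unbound": float(delta[~bound].median()),
               "spearman": corr.to_dict()}
    (outdir / "enrich_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))


def _stage_patterns(cfg: PipelineConfig, outdir: Path) -> None:
    _require(outdir, "patterns", "te_counts.tsv", "families.tsv")
    te = CountMatrix.from_tsv(outdir / "te_counts.tsv")
    kept = min_reads_filter(te.counts, cfg.min_reads)
    te_kept = CountMatrix(counts=kept, lib_sizes=te.lib_sizes)
    cpm = normalize_logcpm(te_kept).cpm
    groups = pd.Series({c: c.rsplit(".r", 1)[0] for c in cpm.columns})
    if cfg.pattern_space == "all":
        specs = enumerate_patterns(sorted(groups.unique()))
    else:
        specs = preset_patterns()
    hyper, _resp, trace = fit_gg_em(cpm, groups, specs)
    assignment = assign_patterns(cpm, groups, hyper, specs)
    out = assignment.posterior.copy()
    out["best_pattern"] = assignment.best_pattern
    _write_tsv(out, outdir / "pattern_assignments.tsv")
    fams = pd.read_csv(outdir / "families.tsv", sep="\t", index_col=0)["family"]
    enr = family_enrichment(assignment, fams)
    enr.to_csv(outdir / "pattern_family_enrichment.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    counts = assignment.best_pattern.value_counts()
    (outdir / "patterns_summary.json").write_text(json.dumps(
        {"hyper": {"alpha": hyper.alpha, "a0": hyper.a0, "nu": hyper.nu},
         "final_loglik": trace[-1],
         "pattern_counts": {k: int(v) for k, v in counts.items()}},
        indent=2, sort_keys=True))


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "annotate": _stage_annotate,
    "classify": _stage_classify,
    "count": _stage_count,
    "de": _stage_de,
    "enrich": _stage_enrich,
    "patterns": _stage_patterns,
}


def run_pipeline(config: PipelineConfig, stages=("all",)) -> dict:
    """Run the requested stages in dependency order and write a manifest.

    ``stages=('all',)`` runs everything.  A stage whose upstream outputs are
    missing (not produced in this run nor found in the output directory)
    raises an error naming the missing piece.
    """
    if isinstance(stages, str):
        stages = (stages,)
    wanted = list(STAGES) if "all" in stages else [s for s in STAGES if s in stages]
    unknown = set(stages) - set(STAGES) - {"all"}
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in wanted:
        log.info("running stage %s", stage)
        _STAGE_FUNCS[stage](config, outdir)
    manifest = {
        "version": __version__,
        "stages": wanted,
        "config": config.to_dict(),
        "input_hashes": {
            name: _sha256(Path(p)) for name, p in sorted(config.inputs.items())
        },
        "output_hashes": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
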