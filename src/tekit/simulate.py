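"""Synthetic fixtures with known ground truth for every pipeline stage.

The generators emulate the shape of the real inputs — RepeatMasker hit
structure with internal fragments and attributed LTRs, six-condition RNA-seq
count matrices (wild-type / DNMT TKO / TET TKO, control or Kap1-knockdown,
with replicates) drawn from the same Gamma-Gamma model the classifier
assumes (Gamma expression mixed through Poisson sampling, so marginal counts
are overdispersed), IP/input pairs with planted enrichment at a designated
bound subset, peak sets overlapping chosen integrants at controlled
reciprocal fractions, and per-CpG percent-methylation tables — while every
simulator also returns the planted truth so recovery can be scored.

All simulators are deterministic functions of (config, seed); independent
random sub-streams are derived by stable hashing of purpose strings.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .patterns import SIX_GROUPS, PatternSpec, preset_patterns
from .quantify import CountMatrix
from .repeats import RepeatHit, TEIntegrant, merge_integrants

__all__ = [
    "SimConfig",
    "SimTruth",
    "rng_for",
    "simulate_repeat_hits",
    "simulate_counts",
    "simulate_two_group_counts",
    "simulate_ip_input",
    "simulate_rrbs_and_peaks",
]

_DEFAULT_FAMILIES = (
    ("IAPEz-int", ("IAPLTR1a_Mm", "IAPLTR2_Mm"), "LTR/ERVK"),
    ("MMERVK10C-int", ("RLTR10C",), "LTR/ERVK"),
    ("MERVL-int", ("MT2_Mm",), "LTR/ERVL"),
    ("ETnERV-int", ("RLTRETN_Mm",), "LTR/ERVK"),
)


@dataclass
class SimConfig:
    """Study-design parameters for all simulators.

    Defaults reflect the six-condition design (3 genotypes x control/knockdown)
    with 3 replicates each, mESC-scale library sizes, moderately dispersed
    Gamma expression (alpha = 10), and clearly separated methylation classes.
    """

    seed: int = 0
    genome: dict = field(default_factory=lambda: {"chr1": 4_000_000, "chr2": 4_000_000})
    families: tuple = _DEFAULT_FAMILIES
    n_integrants_per_family: int = 60
    internal_len: tuple = (2000, 5000)  # bp range of internal fragments
    ltr_len: tuple = (300, 450)
    gap_choices: tuple = (50, 100, 200, 400)  # within the 400 bp merge rule by default
    merge_truth_gap: int = 400  # gaps above this split the planted truth grouping
    detached_gap: int = 500  # beyond the merge rule: stays a solo LTR
    solo_ltr_prob: float = 0.15
    detached_ltr_prob: float = 0.10
    fragmented_internal_prob: float = 0.15
    spacing: int = 2000  # between integrants, > max merge gap

    groups: tuple = SIX_GROUPS
    replicates: int = 3
    lib_size: int = 20_000_000
    pattern_mixture: dict = field(
        default_factory=lambda: {"P0": 0.40, "P1": 0.25, "P2": 0.10, "P3": 0.10, "P4": 0.10, "P5": 0.05}
    )
    alpha: float = 10.0  # observation Gamma shape
    a0: float = 5.0  # prior shape on block rates
    nu: float = 0.5  # prior rate on block rates
    block_mean_ratio: float | None = 4.0  # None -> draw block rates from the prior
    base_cpm: tuple = (2.0, 30.0)  # log-uniform range of baseline expression

    bound_fraction: float = 0.4
    enrichment_effect: float = 1.0  # planted log2 IP gain at bound loci upon knockdown
    baseline_enrichment: float = 0.5
    ip_coverage: float = 100.0  # expected input reads per region
    ip_lib_size: int = 1_000_000
    peak_fraction: float = 0.30  # peak length as a fraction of its integrant
    cpg_density: float = 0.01  # CpGs per bp
    meth_beta_conc: float = 10.0
    meth_mean_bound: float = 80.0  # percent
    meth_mean_unbound: float = 10.0

    def __post_init__(self) -> None:
        if abs(sum(self.pattern_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("pattern_mixture proportions must sum to 1")
        if self.lib_size <= 0 or self.ip_lib_size <= 0:
            raise ValueError("library sizes must be positive")
        if self.replicates < 1 or self.n_integrants_per_family < 1:
            raise ValueError("counts must be positive")


@dataclass
class SimTruth:
    """Planted ground truth: one row per integrant/feature."""

    integrants: pd.DataFrame = field(default_factory=pd.DataFrame)
    hit_membership: pd.DataFrame = field(default_factory=pd.DataFrame)  # hit_id -> truth group
    patterns: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    bound: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))
    enrichment_delta: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    methylation_mean: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def rng_for(seed: int, purpose: str) -> np.random.Generator:
    """Independent reproducible stream for one simulator purpose."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(purpose.encode())]))


# ---------------------------------------------------------------------------
# RepeatMasker hits
# ---------------------------------------------------------------------------

def simulate_repeat_hits(config: SimConfig) -> tuple[list[RepeatHit], dict, SimTruth]:
    """Internal fragments with flanking LTRs at controlled gaps.

    Returns (hits, pairing table, truth); the truth's ``hit_membership`` maps
    every hit to the integrant it belongs to, with detached LTRs (placed
    beyond the merge gap) recorded as their own solo integrants.
    """
    rng = rng_for(config.seed, "repeat_hits")
    hits: list[RepeatHit] = []
    pairing = {fam: set(ltrs) for fam, ltrs, _ in config.families}
    rows = []
    membership = []
    hid = 0
    group_id = 0
    chroms = list(config.genome)
    cursors = {c: 1000 for c in chroms}
    per_chrom = {c: 0 for c in chroms}

    def new_hit(chrom, start, end, strand, name, cls):
        nonlocal hid
        hid += 1
        h = RepeatHit(chrom=chrom, start=start, end=end, strand=strand, repeat_name=name,
                      repeat_class_family=cls, sw_score=int(rng.integers(500, 20000)), hit_id=f"h{hid}")
        hits.append(h)
        return h

    for fam_name, ltr_names, cls in config.families:
        for _ in range(config.n_integrants_per_family):
            chrom = chroms[int(rng.integers(len(chroms)))]
            strand = "+" if rng.random() < 0.5 else "-"
            pos = cursors[chrom]
            u = rng.random()

            def open_group(family: str, kind: str) -> str:
                nonlocal group_id
                group_id += 1
                name = f"G{group_id:05d}"
                rows.append({"truth_group": name, "family": family, "chrom": chrom,
                             "strand": strand, "kind": kind})
                return name

            def place(length: int, name: str, gname: str) -> None:
                nonlocal pos
                h = new_hit(chrom, pos, pos + length - 1, strand, name, cls)
                membership.append({"hit_id": h.hit_id, "truth_group": gname})
                pos += length

            if u < config.solo_ltr_prob:
                ltr = ltr_names[int(rng.integers(len(ltr_names)))]
                place(int(rng.integers(*config.ltr_len)), ltr, open_group(ltr, "solo_ltr"))
            else:
                # a provirus: LTR5, internal (possibly fragmented), LTR3; a gap
                # above merge_truth_gap breaks the planted grouping right there
                ltr = ltr_names[int(rng.integers(len(ltr_names)))]
                gname = open_group(fam_name, "provirus")
                place(int(rng.integers(*config.ltr_len)), ltr, gname)

                def advance(gap: int) -> None:
                    nonlocal pos, gname
                    pos += gap
                    if gap > config.merge_truth_gap:
                        gname = open_group(fam_name, "fragment")

                advance(int(rng.choice(config.gap_choices)))
                if rng.random() < config.fragmented_internal_prob:
                    place(int(rng.integers(*config.internal_len)) // 2, fam_name, gname)
                    advance(int(rng.choice(config.gap_choices)))
                    place(int(rng.integers(*config.internal_len)) // 2, fam_name, gname)
                else:
                    place(int(rng.integers(*config.internal_len)), fam_name, gname)
                if rng.random() < config.detached_ltr_prob:
                    # 3' LTR drifted beyond the merge rule: its own solo integrant
                    pos += config.detached_gap
                    place(int(rng.integers(*config.ltr_len)), ltr, open_group(ltr, "detached_ltr"))
                else:
                    advance(int(rng.choice(config.gap_choices)))
                    place(int(rng.integers(*config.ltr_len)), ltr, gname)
            pos += config.spacing + int(rng.integers(0, 2000))
            cursors[chrom] = pos
            per_chrom[chrom] += 1
            if pos >= config.genome[chrom] - 20000:
                raise ValueError(f"simulated integrants exceed {chrom} bounds; enlarge the genome")
    truth = SimTruth(
        integrants=pd.DataFrame(rows).set_index("truth_group"),
        hit_membership=pd.DataFrame(membership).set_index("hit_id"),
    )
    hits.sort(key=lambda h: (h.chrom, h.start))
    return hits, pairing, truth


# ---------------------------------------------------------------------------
# counts under the Gamma-Gamma pattern model
# ---------------------------------------------------------------------------

def _pattern_map(config: SimConfig) -> dict[str, PatternSpec]:
    return {p.id: p for p in preset_patterns(config.groups)}

def _sample_columns(config: SimConfig) -> list[str]:
    return [f"{g}.r{r + 1}" for g in config.groups for r in range(config.replicates)]


def simulate_counts(
    config: SimConfig, feature_ids: list[str], rng_purpose: str = "counts"
) -> tuple[CountMatrix, pd.Series]:
    """Six-condition counts with planted expression patterns.

    Per feature: draw a pattern from the mixture; give every block its own
    mean expression — either rate beta ~ Gamma(a0, nu) from the prior
    (``block_mean_ratio=None``) or controlled geometric separation where
    distinct blocks differ by the configured ratio; draw per-replicate
    expression x ~ Gamma(alpha, beta) in CPM units and counts ~
    Poisson(x * lib_size / 1e6).  Returns the matrix and true pattern labels.
    """
    rng = rng_for(config.seed, rng_purpose)
    pmap = _pattern_map(config)
    ids = list(config.pattern_mixture)
    probs = np.array([config.pattern_mixture[i] for i in ids])
    cols = _sample_columns(config)
    col_group = [c.rsplit(".r", 1)[0] for c in cols]
    n_feat = len(feature_ids)
    chosen = rng.choice(len(ids), size=n_feat, p=probs)
    counts = np.zeros((n_feat, len(cols)), dtype=np.int64)
    base = np.exp(rng.uniform(np.log(config.base_cpm[0]), np.log(config.base_cpm[1]), size=n_feat))
    for i in range(n_feat):
        spec = pmap[ids[chosen[i]]]
        if config.block_mean_ratio is None:
            betas = {b: rng.gamma(config.a0, 1.0 / config.nu) for b in spec.blocks}
            means = {b: config.alpha / betas[b] for b in spec.blocks}
        else:
            order = rng.permutation(spec.n_blocks)
            means = {b: base[i] * config.block_mean_ratio ** order[j] for j, b in enumerate(spec.blocks)}
        for j, g in enumerate(col_group):
            block = next(b for b in spec.blocks if g in b)
            x = rng.gamma(config.alpha, means[block] / config.alpha)
            counts[i, j] = rng.poisson(x * config.lib_size / 1e6)
    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(feature_ids, name="feature_id"), columns=cols),
        lib_sizes=pd.Series(config.lib_size, index=cols),
    )
    patterns = pd.Series([ids[c] for c in chosen], index=matrix.counts.index, name="true_pattern")
    return matrix, patterns


def simulate_gg_expression(
    n_features: int,
    pattern: PatternSpec,
    alpha: float = 10.0,
    a0: float = 5.0,
    nu: float = 0.5,
    groups=SIX_GROUPS,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Strictly positive expression drawn exactly from the Gamma-Gamma model.

    Per feature and block: rate beta ~ Gamma(a0, nu); per observation
    x ~ Gamma(alpha, beta).  No Poisson counting layer — this is the model's
    own generative process, the reference case for hyperparameter recovery
    (the count-level simulators add sampling noise on top).
    """
    rng = np.random.default_rng(seed)
    cols = [f"{g}.r{r + 1}" for g in groups for r in range(replicates)]
    col_block = [next(i for i, b in enumerate(pattern.blocks) if c.rsplit(".r", 1)[0] in b) for c in cols]
    betas = rng.gamma(a0, 1.0 / nu, size=(n_features, pattern.n_blocks))
    x = np.empty((n_features, len(cols)))
    for j, bi in enumerate(col_block):
        x[:, j] = rng.gamma(alpha, 1.0 / betas[:, bi])
    ids = pd.Index([f"TE{i + 1:05d}" for i in range(n_features)], name="feature_id")
    return pd.DataFrame(x, index=ids, columns=cols)


def simulate_two_group_counts(
    n_features: int,
    n_per_group: int = 3,
    frac_changed: float = 0.1,
    fold: float = 4.0,
    alpha: float = 10.0,
    base_cpm: tuple = (5.0, 50.0),
    lib_size: int = 20_000_000,
    seed: int = 0,
) -> tuple[CountMatrix, pd.Series]:
    """Two-condition counts with a planted fraction of fold-changed features.

    The same Gamma->Poisson scheme as :func:`simulate_counts`; changed
    features are upregulated by ``fold`` in the second group.  Returns the
    matrix and a boolean truth Series.
    """
    rng = np.random.default_rng(seed)
    cols = [f"ctrl.r{i + 1}" for i in range(n_per_group)] + [f"kd.r{i + 1}" for i in range(n_per_group)]
    base = np.exp(rng.uniform(np.log(base_cpm[0]), np.log(base_cpm[1]), size=n_features))
    changed = rng.random(n_features) < frac_changed
    counts = np.zeros((n_features, 2 * n_per_group), dtype=np.int64)
    for i in range(n_features):
        for j in range(2 * n_per_group):
            mean = base[i] * (fold if (changed[i] and j >= n_per_group) else 1.0)
            x = rng.gamma(alpha, mean / alpha)
            counts[i, j] = rng.poisson(x * lib_size / 1e6)
    ids = pd.Index([f"TE{i + 1:05d}" for i in range(n_features)], name="feature_id")
    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=ids, columns=cols),
        lib_sizes=pd.Series(lib_size, index=cols),
    )
    return matrix, pd.Series(changed, index=ids, name="true_changed")


# ---------------------------------------------------------------------------
# IP/input pairs
# ---------------------------------------------------------------------------

def simulate_ip_input(
    config: SimConfig, region_ids: list[str], bound: pd.Series | None = None
) -> tuple[dict[tuple[str, str], CountMatrix], SimTruth]:
    """Paired IP/input counts for control and knockdown conditions.

    Bound regions gain ``enrichment_effect`` log2 units of IP signal in the
    knockdown only; all regions share the baseline enrichment in control.
    Counts are Poisson around ``ip_coverage`` expected input reads.
    """
    rng = rng_for(config.seed, "ip_input")
    n = len(region_ids)
    if bound is None:
        bound = pd.Series(rng.random(n) < config.bound_fraction, index=region_ids)
    bound = bound.astype(bool)
    idx = pd.Index(region_ids, name="region_id")
    out: dict[tuple[str, str], CountMatrix] = {}
    for cond in ("ctrl", "kd"):
        enr = np.full(n, 2.0 ** config.baseline_enrichment)
        if cond == "kd":
            enr = enr * np.where(bound.to_numpy(), 2.0 ** config.enrichment_effect, 1.0)
        input_mean = np.full(n, config.ip_coverage)
        ip_mean = input_mean * enr
        for kind, mean in (("ip", ip_mean), ("input", input_mean)):
            counts = rng.poisson(mean).astype(np.int64)
            out[(cond, kind)] = CountMatrix(
                counts=pd.DataFrame({f"{cond}_{kind}": counts}, index=idx),
                lib_sizes=pd.Series(config.ip_lib_size, index=[f"{cond}_{kind}"]),
            )
    delta = pd.Series(np.where(bound, config.enrichment_effect, 0.0), index=idx, name="true_delta")
    return out, SimTruth(bound=bound, enrichment_delta=delta)


# ---------------------------------------------------------------------------
# RRBS CpGs and peak BEDs
# ---------------------------------------------------------------------------

def simulate_rrbs_and_peaks(
    config: SimConfig, integrants: list[TEIntegrant], bound: pd.Series
) -> tuple[pd.DataFrame, dict[str, list[GenomicInterval]], SimTruth]:
    """Per-CpG methylation tables and peak BEDs anchored on the integrants.

    CpGs are placed at the configured density inside every integrant; percent
    methylation is Beta-distributed with class means set by the bound flag.
    Peaks cover each bound integrant with a centered sub-interval spanning
    ``peak_fraction`` of its length, so reciprocal-overlap classification at
    a threshold below that fraction flags exactly the bound set.
    """
    rng = rng_for(config.seed, "rrbs_peaks")
    conc = config.meth_beta_conc
    cpg_rows = []
    peaks: list[GenomicInterval] = []
    meth_mean = {}
    for t in integrants:
        is_bound = bool(bound.get(t.integrant_id, False))
        mean_pct = config.meth_mean_bound if is_bound else config.meth_mean_unbound
        meth_mean[t.integrant_id] = mean_pct
        mu = mean_pct / 100.0
        n_cpg = max(1, rng.poisson(config.cpg_density * t.length))
        pos = np.sort(rng.integers(t.start, t.end, size=n_cpg))
        pct = 100.0 * rng.beta(mu * conc, (1 - mu) * conc, size=n_cpg)
        for p, m in zip(pos, pct):
            cpg_rows.append({"chrom": t.chrom, "start": int(p), "end": int(p) + 1, "percent": float(m)})
        if is_bound:
            plen = max(1, int(round(config.peak_fraction * t.length)))
            mid = (t.start + t.end) // 2
            ps = max(t.start, mid - plen // 2)
            peaks.append(GenomicInterval(chrom=t.chrom, start=ps, end=ps + plen, name=f"peak_{t.integrant_id}"))
    cpg_table = pd.DataFrame(cpg_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    truth = SimTruth(bound=bound.astype(bool), methylation_mean=pd.Series(meth_mean, name="true_meth_mean"))
    return cpg_table, {"kap1": peaks}, truth
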