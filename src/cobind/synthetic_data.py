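"""Synthetic regulatory genomes with planted, fully recorded ground truth.

The generator emits everything the analysis stages consume — genome FASTA,
gene models, peaks, per-peak count matrices and DEG tables — with statistical
structure matching what the pipeline assumes: peaks enriched 5' of TSSs,
0-3 copies of each planted motif per peak with characteristic inter-motif
spacings, negative-binomial counts with a planted condition effect biased
toward G-box peaks, and DEG tables with a planted shared set of which a
planted subset is the "cooperative" truth.  Every planted quantity is
recorded in a TruthBundle so recovery can be checked exactly.

Determinism contract: a SimConfig (including its seed) maps to byte-identical
outputs.  One SeedSequence is spawned into independent child streams in a
fixed order (genome, genes, peaks, motifs, scores, counts, degs), so adding
draws inside one stage never perturbs another.

Planting rewrites sequence in place (never inserts), so coordinates cannot
shift.  After writing, each peak is rescanned; if writing or the random
background produced extra matches of any planned motif, the peak background
is redrawn and replanted (bounded retries), guaranteeing that the scanner's
view of each peak equals the planted truth exactly.
"""

from __future__ import annotations

import json
import math
from bisect import bisect_left, insort
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    CountMatrix,
    DEGTable,
    GeneModel,
    GenomicInterval,
    Peak,
    write_count_matrix,
    write_deg_table,
    write_fasta,
    write_genes,
    write_peaks,
)
from .motif_architecture import IUPAC, MotifSpec, scan_motif

__all__ = [
    "MotifPlan",
    "DEGPlan",
    "SimConfig",
    "TruthBundle",
    "SimResult",
    "generate_genome",
    "generate_peaks",
    "plant_motifs",
    "assign_scores",
    "simulate_counts",
    "simulate_deg_tables",
    "simulate_all",
    "write_outputs",
    "verify_truth",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class MotifPlan:
    """How many copies of one motif to plant per peak and how to space them."""

    name: str
    consensus: str
    count_probs: tuple[float, ...]  # P(0), P(1), P(2), P(3) copies
    spacing_mean: float
    spacing_sd: float

    def __post_init__(self):
        if abs(sum(self.count_probs) - 1.0) > 1e-9:
            raise ValueError(f"count_probs for {self.name} must sum to 1")
        if any(p < 0 for p in self.count_probs):
            raise ValueError("count_probs must be >= 0")
        MotifSpec(self.name, self.consensus)  # validates the consensus

    @property
    def spec(self) -> MotifSpec:
        return MotifSpec(self.name, self.consensus)


@dataclass(frozen=True)
class DEGPlan:
    """Per-genotype DEG table plan."""

    n_deg: int = 60
    frac_up: float = 0.5

    def __post_init__(self):
        if self.n_deg < 0 or not (0 <= self.frac_up <= 1):
            raise ValueError("bad DEG plan")


def _default_motif_plans() -> tuple[MotifPlan, ...]:
    # Count distributions echo the observed per-peak motif content of the
    # system being emulated (~20% of peaks with one G-box, ~9% with more;
    # ~87% with two or more DOF motifs, max three) and the 25/15 bp spacing
    # modes.
    return (
        MotifPlan("gbox", "CACGTG", (0.71, 0.20, 0.06, 0.03), 25.0, 5.0),
        MotifPlan("dof", "AAAAG", (0.05, 0.08, 0.50, 0.37), 15.0, 4.0),
    )


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one synthetic dataset."""

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 500_000
    base_composition: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    n_genes: int = 300
    gene_length_range: tuple[int, int] = (500, 2500)
    n_peaks: int = 600
    peak_length_mean: float = 300.0
    peak_length_sd: float = 50.0
    min_peak_length: int = 50
    promoter_fraction: float = 0.8
    promoter_window: int = 3000
    motif_plans: tuple[MotifPlan, ...] = field(default_factory=_default_motif_plans)
    score_base: float = 5.0
    score_per_gbox: float = 2.0
    score_noise_sd: float = 1.0
    n_replicates: int = 3
    nb_mean: float = 100.0
    nb_dispersion: float = 0.1
    affected_fraction: float = 0.1
    effect_log2fc: float = -2.0
    conditions: tuple[str, str] = ("wild_type", "pif4")
    deg_plans: Mapping[str, DEGPlan] = field(
        default_factory=lambda: {"pif4": DEGPlan(), "cdfq": DEGPlan()}
    )
    n_shared_degs: int = 30
    n_cooperative: int = 10
    frac_opposite: float = 0.1
    pif4_target_fraction: float = 0.3
    max_plant_retries: int = 100

    def __post_init__(self):
        # coerce plain-dict plans (e.g. from YAML configs) into plan objects
        if self.motif_plans and isinstance(self.motif_plans[0], dict):
            object.__setattr__(
                self, "motif_plans", tuple(MotifPlan(**p) for p in self.motif_plans)
            )
        if self.deg_plans and any(isinstance(v, dict) for v in self.deg_plans.values()):
            object.__setattr__(
                self,
                "deg_plans",
                {
                    k: (DEGPlan(**v) if isinstance(v, dict) else v)
                    for k, v in self.deg_plans.items()
                },
            )
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        if any(p < 0 for p in self.base_composition):
            raise ValueError("base_composition must be >= 0")
        for name, val in (
            ("n_chrom", self.n_chrom),
            ("chrom_length", self.chrom_length),
            ("n_genes", self.n_genes),
            ("n_peaks", self.n_peaks),
        ):
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        for name, val in (
            ("promoter_fraction", self.promoter_fraction),
            ("affected_fraction", self.affected_fraction),
            ("frac_opposite", self.frac_opposite),
            ("pif4_target_fraction", self.pif4_target_fraction),
        ):
            if not (0 <= val <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.seed < 0:
            raise ValueError("seed must be >= 0")


@dataclass
class TruthBundle:
    """Planted parameters of one synthetic dataset — the recovery oracle."""

    motif_positions: dict[str, dict[str, list[int]]] = field(default_factory=dict)
    spacing_draws: dict[str, list[int]] = field(default_factory=dict)
    gbox_count: dict[str, int] = field(default_factory=dict)
    promoter_peaks: dict[str, str] = field(default_factory=dict)  # peak -> gene
    score_plan: dict[str, float] = field(default_factory=dict)
    affected_peaks: dict[str, float] = field(default_factory=dict)  # peak -> log2fc
    size_factors: dict[str, float] = field(default_factory=dict)
    deg_sets: dict[str, dict[str, int]] = field(default_factory=dict)
    shared_degs: list[str] = field(default_factory=list)
    cooperative_genes: list[str] = field(default_factory=list)
    cooperative_peaks: dict[str, list[str]] = field(default_factory=dict)  # gene -> peaks
    pif4_target_genes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class SimResult:
    config: SimConfig
    genome: dict[str, str]
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    peaks: list[Peak]
    counts: CountMatrix
    deg_tables: dict[str, DEGTable]
    pif4_targets: set[str]
    truth: TruthBundle


def _rng_streams(seed: int) -> dict[str, np.random.Generator]:
    names = ["genome", "genes", "peaks", "motifs", "scores", "counts", "degs"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# genome and genes


class _Placer:
    """Non-overlapping interval placement with rejection sampling."""

    def __init__(self):
        self.by_chrom: dict[str, list[tuple[int, int]]] = {}

    def fits(self, chrom: str, start: int, end: int) -> bool:
        ivs = self.by_chrom.setdefault(chrom, [])
        i = bisect_left(ivs, (start, end))
        if i > 0 and ivs[i - 1][1] > start:
            return False
        if i < len(ivs) and ivs[i][0] < end:
            return False
        return True

    def add(self, chrom: str, start: int, end: int) -> None:
        insort(self.by_chrom.setdefault(chrom, []), (start, end))


def _random_sequence(rng, length: int, probs) -> np.ndarray:
    return rng.choice(4, size=length, p=np.asarray(probs, dtype=float))


def generate_genome(
    config: SimConfig, rng_genome=None, rng_genes=None
) -> tuple[dict[str, str], list[GeneModel]]:
    """I.i.d. background genome plus non-overlapping stranded genes."""
    if rng_genome is None or rng_genes is None:
        streams = _rng_streams(config.seed)
        rng_genome = rng_genome or streams["genome"]
        rng_genes = rng_genes or streams["genes"]
    genome: dict[str, str] = {}
    for c in range(config.n_chrom):
        idx = _random_sequence(rng_genome, config.chrom_length, config.base_composition)
        genome[f"chr{c + 1}"] = "".join(_BASES[idx])
    chroms = list(genome)
    placer = _Placer()
    genes: list[GeneModel] = []
    lo, hi = config.gene_length_range
    max_tries = 200 * config.n_genes
    tries = 0
    while len(genes) < config.n_genes:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {config.n_genes} non-overlapping genes after "
                f"{max_tries} tries; use longer chromosomes or fewer genes"
            )
        tries += 1
        chrom = chroms[rng_genes.integers(len(chroms))]
        length = int(rng_genes.integers(lo, hi + 1))
        if length > config.chrom_length:
            continue
        start = int(rng_genes.integers(0, config.chrom_length - length + 1))
        if not placer.fits(chrom, start, start + length):
            continue
        placer.add(chrom, start, start + length)
        strand = "+" if rng_genes.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                id=f"gene_{len(genes) + 1:04d}",
                interval=GenomicInterval(chrom, start, start + length, strand),
            )
        )
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start))
    return genome, genes


# ---------------------------------------------------------------------------
# peaks


def generate_peaks(
    config: SimConfig,
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    rng=None,
) -> tuple[list[Peak], dict[str, str]]:
    """Place peaks: a promoter fraction with centers within the upstream
    window 5' of a random TSS (gene orientation respected), the rest uniform.

    Peaks are kept non-overlapping so that motif planting in one peak can
    never corrupt another.  Returns the peaks (scores zero at this stage) and
    the promoter-peak -> gene truth map.
    """
    rng = rng if rng is not None else _rng_streams(config.seed)["peaks"]
    chroms = list(chrom_sizes)
    placer = _Placer()
    n_prom = math.ceil(config.promoter_fraction * config.n_peaks)
    peaks: list[Peak] = []
    promoter_truth: dict[str, str] = {}
    max_tries = 500 * config.n_peaks
    tries = 0

    def draw_length() -> int:
        while True:
            ln = int(round(rng.normal(config.peak_length_mean, config.peak_length_sd)))
            if ln >= config.min_peak_length:
                return ln

    while len(peaks) < config.n_peaks:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {config.n_peaks} non-overlapping peaks after "
                f"{max_tries} tries; enlarge the genome or shrink peaks"
            )
        tries += 1
        length = draw_length()
        want_promoter = len(peaks) < n_prom
        gene_id = None
        if want_promoter:
            if not genes:
                raise ValueError("promoter placement requested with no genes")
            g = genes[rng.integers(len(genes))]
            d = int(rng.integers(1, config.promoter_window + 1))
            center = g.tss - d if g.interval.strand == "+" else g.tss + d
            start = center - length // 2
            csize = chrom_sizes[g.interval.chrom]
            if start < 0 or start + length > csize:
                continue
            chrom = g.interval.chrom
            gene_id = g.id
        else:
            weights = np.array(
                [max(chrom_sizes[c] - length + 1, 0) for c in chroms], dtype=float
            )
            if weights.sum() == 0:
                continue
            chrom = chroms[rng.choice(len(chroms), p=weights / weights.sum())]
            start = int(rng.integers(0, chrom_sizes[chrom] - length + 1))
        if not placer.fits(chrom, start, start + length):
            continue
        placer.add(chrom, start, start + length)
        pid = f"peak_{len(peaks) + 1:04d}"
        peaks.append(Peak(id=pid, interval=GenomicInterval(chrom, start, start + length)))
        if gene_id is not None:
            promoter_truth[pid] = gene_id
    return peaks, promoter_truth


# ---------------------------------------------------------------------------
# motif planting


def _concretize(consensus: str, rng) -> str:
    return "".join(
        c if len(IUPAC[c]) == 1 else sorted(IUPAC[c])[rng.integers(len(IUPAC[c]))]
        for c in consensus
    )


def _draw_gaps(plan: MotifPlan, k: int, rng) -> list[int]:
    gaps = []
    floor = len(plan.consensus) + 1
    for _ in range(k - 1):
        while True:
            gp = int(round(rng.normal(plan.spacing_mean, plan.spacing_sd)))
            if gp >= floor:
                gaps.append(gp)
                break
    return gaps


def plant_motifs(
    genome: Mapping[str, str],
    peaks: Sequence[Peak],
    config: SimConfig,
    rng=None,
) -> tuple[dict[str, str], TruthBundle]:
    """Write planted motif instances into each peak and record the truth.

    Per peak and motif plan, a copy number k is drawn and k instances are
    written with consecutive start-to-start gaps from the spacing
    distribution (truncated at >= motif length + 1).  The peak is then
    rescanned; if the scan of any planned motif differs from the plant (a
    chance background match, a collision between motifs, or a match created
    across a planted edge) the peak background is redrawn and replanted, up
    to ``max_plant_retries`` times, then an error names the peak.
    """
    rng = rng if rng is not None else _rng_streams(config.seed)["motifs"]
    arrays = {c: np.array(list(s)) for c, s in genome.items()}
    truth = TruthBundle()
    specs = [p.spec for p in config.motif_plans]

    for peak in peaks:
        iv = peak.interval
        plen = len(iv)
        ks = [
            int(rng.choice(len(plan.count_probs), p=plan.count_probs))
            for plan in config.motif_plans
        ]
        for plan, k in zip(config.motif_plans, ks):
            min_span = k * len(plan.consensus) + max(k - 1, 0)
            if min_span > plen:
                raise ValueError(
                    f"peak {peak.id}: cannot fit {k} copies of {plan.name} "
                    f"in {plen} bp"
                )
        for attempt in range(config.max_plant_retries):
            background = _random_sequence(rng, plen, config.base_composition)
            local = _BASES[background].copy()
            planted: dict[str, list[int]] = {}
            gap_draws: dict[str, list[int]] = {}
            occupied: list[tuple[int, int]] = []
            ok = True
            for plan, k in zip(config.motif_plans, ks):
                planted[plan.name] = []
                gap_draws[plan.name] = []
                if k == 0:
                    continue
                m = len(plan.consensus)
                placed = False
                for _ in range(20):  # position attempts within this background
                    gaps = _draw_gaps(plan, k, rng)
                    span = sum(gaps) + m
                    if span > plen:
                        continue
                    first = int(rng.integers(0, plen - span + 1))
                    offs = [first]
                    for gp in gaps:
                        offs.append(offs[-1] + gp)
                    runs = [(o, o + m) for o in offs]
                    if any(
                        a < oe and b > ob for a, b in runs for ob, oe in occupied
                    ):
                        continue
                    for o in offs:
                        local[o : o + m] = list(_concretize(plan.consensus, rng))
                    occupied.extend(runs)
                    planted[plan.name] = offs
                    gap_draws[plan.name] = gaps
                    placed = True
                    break
                if not placed:
                    ok = False
                    break
            if ok:
                seq = "".join(local)
                for spec, plan in zip(specs, config.motif_plans):
                    hits = scan_motif(seq, spec, peak.id, count_policy="all")
                    if sorted(h.offset for h in hits) != sorted(planted[plan.name]):
                        ok = False
                        break
            if ok:
                arrays[iv.chrom][iv.start : iv.end] = local
                truth.motif_positions[peak.id] = planted
                truth.gbox_count[peak.id] = len(planted.get("gbox", []))
                for plan in config.motif_plans:
                    truth.spacing_draws.setdefault(plan.name, []).extend(
                        gap_draws[plan.name]
                    )
                break
        else:
            raise ValueError(
                f"peak {peak.id}: could not satisfy the motif plan in "
                f"{config.max_plant_retries} redraws"
            )
    new_genome = {c: "".join(a) for c, a in arrays.items()}
    return new_genome, truth


def assign_scores(
    peaks: Sequence[Peak], truth: TruthBundle, config: SimConfig, rng=None
) -> list[Peak]:
    """Scores linear in planted G-box count plus Gaussian noise (truncated > 0)."""
    rng = rng if rng is not None else _rng_streams(config.seed)["scores"]
    truth.score_plan = {
        "base": config.score_base,
        "per_gbox": config.score_per_gbox,
        "noise_sd": config.score_noise_sd,
    }
    out = []
    for p in peaks:
        k = truth.gbox_count.get(p.id, 0)
        score = config.score_base + config.score_per_gbox * k + rng.normal(
            0, config.score_noise_sd
        )
        out.append(
            Peak(
                id=p.id,
                interval=p.interval,
                summit_offset=p.summit_offset,
                score=max(score, 1e-3),
            )
        )
    return out


# ---------------------------------------------------------------------------
# counts


def simulate_counts(
    peaks: Sequence[Peak],
    config: SimConfig,
    truth: TruthBundle,
    rng=None,
    forced_affected: Sequence[str] = (),
) -> CountMatrix:
    """Negative-binomial count matrix with a planted condition effect.

    Counts are NB with mean nb_mean * sizefactor_j * 2^Delta_i where Delta_i
    is ``effect_log2fc`` in the second condition for affected peaks and 0
    otherwise; var = mu + dispersion * mu^2 (Gamma-Poisson mixture; the
    dispersion -> 0 limit is Poisson).  Size factors are log-uniform in
    [0.7, 1.4].  Affected peaks are drawn preferentially from peaks planted
    with at least one G-box; ``forced_affected`` peak ids are always affected.
    """
    if config.n_replicates < 2:
        raise ValueError("need at least 2 replicates per condition")
    rng = rng if rng is not None else _rng_streams(config.seed)["counts"]
    # independent substreams: which peaks are affected vs the count noise, so
    # configurations with identical means yield identical matrices
    rng, rng_noise = rng.spawn(2)
    n = len(peaks)
    n_affected = int(round(config.affected_fraction * n))
    forced = [p.id for p in peaks if p.id in set(forced_affected)]
    with_gbox = [
        p.id
        for p in peaks
        if truth.gbox_count.get(p.id, 0) >= 1 and p.id not in set(forced)
    ]
    rng.shuffle(with_gbox)
    affected = list(forced)
    affected.extend(with_gbox[: max(n_affected - len(affected), 0)])
    if len(affected) < n_affected:
        rest = [p.id for p in peaks if p.id not in set(affected)]
        rng.shuffle(rest)
        affected.extend(rest[: n_affected - len(affected)])
    affected_set = set(affected)
    truth.affected_peaks = {
        pid: (config.effect_log2fc if pid in affected_set else 0.0)
        for pid in affected_set
    }

    cond1, cond2 = config.conditions
    samples = [f"{c}_rep{r + 1}" for c in (cond1, cond2) for r in range(config.n_replicates)]
    cond_of = {s: (cond1 if s.startswith(cond1) else cond2) for s in samples}
    sf = np.exp(rng_noise.uniform(np.log(0.7), np.log(1.4), size=len(samples)))
    truth.size_factors = {s: float(f) for s, f in zip(samples, sf)}

    delta = np.array(
        [config.effect_log2fc if p.id in affected_set else 0.0 for p in peaks]
    )
    in_cond2 = np.array([cond_of[s] == cond2 for s in samples])
    mu = config.nb_mean * sf[None, :] * np.power(
        2.0, delta[:, None] * in_cond2[None, :]
    )
    if config.nb_dispersion > 0:
        shape = 1.0 / config.nb_dispersion
        lam = rng_noise.gamma(shape, mu / shape)
        counts = rng_noise.poisson(lam)
    else:
        counts = rng_noise.poisson(mu)
    import pandas as pd

    df = pd.DataFrame(counts, index=[p.id for p in peaks], columns=samples)
    return CountMatrix(counts=df, condition_of=cond_of)


# ---------------------------------------------------------------------------
# DEG tables


def _deg_log2fc(direction: int, rng, lfc_cut: float) -> float:
    return direction * (lfc_cut * 1.01 + rng.exponential(0.7))


def simulate_deg_tables(
    genes: Sequence[GeneModel],
    config: SimConfig,
    truth: TruthBundle,
    bound_gene_ids: set[str],
    rng=None,
) -> tuple[dict[str, DEGTable], set[str]]:
    """DEG tables per genotype with a planted shared set and cooperative core.

    The shared DEG set is the planted cooperative genes plus filler genes
    chosen outside every binding-evidence layer, so that downstream
    intersection can recover exactly the cooperative truth.  Also builds the
    partner-factor (PIF4) target gene set: the cooperative genes plus a
    random fraction of other genes, excluding the fillers.
    """
    rng = rng if rng is not None else _rng_streams(config.seed)["degs"]
    import pandas as pd

    gene_ids = [g.id for g in genes]
    genotypes = list(config.deg_plans)
    if len(genotypes) != 2:
        raise ValueError("need exactly 2 genotypes in deg_plans")
    n_shared = config.n_shared_degs
    coop = list(truth.cooperative_genes)
    if n_shared < len(coop):
        raise ValueError("n_shared_degs smaller than the cooperative set")
    for gt in genotypes:
        if config.deg_plans[gt].n_deg < n_shared:
            raise ValueError(
                f"requested shared overlap {n_shared} larger than DEG set of {gt}"
            )

    unbound_pool = [g for g in gene_ids if g not in bound_gene_ids and g not in coop]
    rng.shuffle(unbound_pool)
    n_filler = n_shared - len(coop)
    if n_filler > len(unbound_pool):
        raise ValueError("not enough unbound genes for the shared-DEG filler")
    fillers = unbound_pool[:n_filler]
    shared = coop + fillers
    truth.shared_degs = sorted(shared)

    remaining = [g for g in gene_ids if g not in set(shared)]
    rng.shuffle(remaining)
    extras: dict[str, list[str]] = {}
    cursor = 0
    for gt in genotypes:
        n_extra = config.deg_plans[gt].n_deg - n_shared
        extras[gt] = remaining[cursor : cursor + n_extra]
        cursor += n_extra
        if len(extras[gt]) < n_extra:
            raise ValueError("not enough genes to fill the requested DEG sets")

    lfc_cut = float(np.log2(1.5))
    # shared-gene directions: genotype A by frac_up, genotype B flipped with
    # probability frac_opposite
    dirs_a = {
        g: (1 if rng.random() < config.deg_plans[genotypes[0]].frac_up else -1)
        for g in shared
    }
    dirs_b = {
        g: (-d if rng.random() < config.frac_opposite else d)
        for g, d in dirs_a.items()
    }
    shared_dirs = {genotypes[0]: dirs_a, genotypes[1]: dirs_b}

    tables: dict[str, DEGTable] = {}
    for gt in genotypes:
        plan = config.deg_plans[gt]
        deg_dirs = dict(shared_dirs[gt])
        for g in extras[gt]:
            deg_dirs[g] = 1 if rng.random() < plan.frac_up else -1
        rows = []
        for g in gene_ids:
            if g in deg_dirs:
                lfc = _deg_log2fc(deg_dirs[g], rng, lfc_cut)
                padj = float(rng.uniform(0.0, 0.049))
            else:
                padj = float(rng.uniform(0.0, 1.0))
                if padj < 0.05:
                    lfc = float(rng.uniform(-0.9, 0.9)) * lfc_cut
                else:
                    lfc = float(rng.normal(0.0, 0.5))
                    if abs(lfc) < 1e-12:
                        lfc = 0.0
            rows.append((g, lfc, padj))
        tables[gt] = DEGTable(
            records=pd.DataFrame(rows, columns=["gene_id", "log2fc", "padj"])
        )
        truth.deg_sets[gt] = deg_dirs

    others = [g for g in gene_ids if g not in set(coop) and g not in set(fillers)]
    n_extra_targets = int(round(config.pif4_target_fraction * len(gene_ids)))
    rng.shuffle(others)
    pif4_targets = set(coop) | set(others[:n_extra_targets])
    truth.pif4_target_genes = sorted(pif4_targets)
    return tables, pif4_targets


# ---------------------------------------------------------------------------
# orchestration


def simulate_all(config: SimConfig) -> SimResult:
    """Run every generator stage in the documented order."""
    streams = _rng_streams(config.seed)
    genome, genes = generate_genome(config, streams["genome"], streams["genes"])
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    peaks, promoter_truth = generate_peaks(config, genes, chrom_sizes, streams["peaks"])
    genome, truth = plant_motifs(genome, peaks, config, streams["motifs"])
    truth.promoter_peaks = promoter_truth
    peaks = assign_scores(peaks, truth, config, streams["scores"])

    # cooperative truth: genes with a G-box-carrying promoter peak.  Genes
    # with two or more promoter peaks are preferred so the planted binding
    # evidence is redundant at the gene level, as it is for real multi-peak
    # target genes; every one of a cooperative gene's promoter peaks is
    # forced into the affected set.
    peaks_of_gene: dict[str, list[str]] = {}
    for pid, gid in promoter_truth.items():
        peaks_of_gene.setdefault(gid, []).append(pid)
    multi = [
        g
        for g, pids in peaks_of_gene.items()
        if len(pids) >= 2 and any(truth.gbox_count.get(p, 0) >= 1 for p in pids)
    ]
    single = [
        g
        for g, pids in peaks_of_gene.items()
        if len(pids) == 1 and truth.gbox_count.get(pids[0], 0) >= 1
    ]
    coop_genes = (multi + single)[: config.n_cooperative]
    if len(coop_genes) < config.n_cooperative:
        raise ValueError(
            "not enough promoter-bound genes with G-box peaks to plant the "
            "cooperative set; raise n_peaks, promoter_fraction or the G-box plan"
        )
    truth.cooperative_genes = sorted(coop_genes)
    truth.cooperative_peaks = {g: sorted(peaks_of_gene[g]) for g in coop_genes}
    forced = [p for g in coop_genes for p in peaks_of_gene[g]]

    counts = simulate_counts(
        peaks, config, truth, streams["counts"], forced_affected=forced
    )
    bound_gene_ids = set(promoter_truth.values())
    deg_tables, pif4_targets = simulate_deg_tables(
        genes, config, truth, bound_gene_ids, streams["degs"]
    )
    return SimResult(
        config=config,
        genome=genome,
        chrom_sizes=chrom_sizes,
        genes=genes,
        peaks=peaks,
        counts=counts,
        deg_tables=deg_tables,
        pif4_targets=pif4_targets,
        truth=truth,
    )


def write_outputs(sim: SimResult, outdir) -> dict[str, Path]:
    """Write the full synthetic dataset as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.gff3",
        "peaks": outdir / "peaks.narrowPeak",
        "counts": outdir / "counts.tsv",
        "pif4_targets": outdir / "pif4_targets.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(sim.genome, paths["genome"])
    write_genes(sim.genes, paths["genes"])
    write_peaks(sim.peaks, paths["peaks"], dialect="narrowPeak")
    write_count_matrix(sim.counts, paths["counts"])
    with open(paths["pif4_targets"], "w") as fh:
        fh.write("gene_id\n")
        for g in sorted(sim.pif4_targets):
            fh.write(g + "\n")
    for gt, table in sim.deg_tables.items():
        p = outdir / f"deg_{gt}.tsv"
        write_deg_table(table, p)
        paths[f"deg_{gt}"] = p
    with open(paths["truth"], "w") as fh:
        fh.write(sim.truth.to_json())
    return paths


def verify_truth(sim: SimResult) -> list[str]:
    """Independently check every truth entry against the emitted records."""
    problems: list[str] = []
    specs = {p.name: p.spec for p in sim.config.motif_plans}
    peak_by_id = {p.id: p for p in sim.peaks}
    for pid, by_motif in sim.truth.motif_positions.items():
        peak = peak_by_id.get(pid)
        if peak is None:
            problems.append(f"truth references unknown peak {pid}")
            continue
        iv = peak.interval
        seq = sim.genome[iv.chrom][iv.start : iv.end]
        for name, offsets in by_motif.items():
            hits = scan_motif(seq, specs[name], pid)
            if sorted(h.offset for h in hits) != sorted(offsets):
                problems.append(f"peak {pid}: scan of {name} != planted positions")
    gene_ids = {g.id for g in sim.genes}
    for gid in sim.truth.cooperative_genes:
        if gid not in gene_ids:
            problems.append(f"cooperative gene {gid} not in gene list")
    for pid in sim.truth.affected_peaks:
        if pid not in peak_by_id:
            problems.append(f"affected peak {pid} not emitted")
    for gt, dirs in sim.truth.deg_sets.items():
        table = sim.deg_tables[gt].records.set_index("gene_id")
        for g in dirs:
            if g not in table.index:
                problems.append(f"DEG {g} missing from table {gt}")
    return problems
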