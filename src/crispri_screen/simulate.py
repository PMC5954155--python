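"""Synthetic CRISPRi screen generator with a planted ground truth.

The generator emulates the statistical structure a pooled dCas9 fitness
screen in a bacterium exhibits: operons of essential/fitness/neutral genes
with promoters; strand-dependent depletion of guides in important genes;
polar silencing of downstream operon genes; a weak short-range (<100 nt)
reverse-polar effect past the stop codon of important genes; seed-specific
(5-mer) toxicity whose strength scales with the cellular dCas9 level;
planted off-target sites sharing >=9 PAM-proximal bases with a guide; and
negative-binomial sequencing counts over a multi-generation growth
competition.  Every per-guide effect is decomposed in a truth ledger so the
analysis stages can be scored against what was planted.

Per-guide effects are expressed directly on the end-vs-start log2
fold-change scale (the aggregate over the whole competition), not as
per-generation fitness; this matches the measured quantity and keeps the
count model analytic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import (
    CONTROL_SPACER,
    GeneAnnotation,
    GenomeRecord,
    annotate_guides,
    control_guide_row,
    extract_guides,
    pam_proximal_base,
    revcomp,
    scan_pams,
    write_annotation_tsv,
    write_genome_fasta,
    write_guides_tsv,
)
from .offtargets import SeedIndex, build_important_classifier, index_genome_seeds

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic screen.

    ``dcas9_level`` rescales concentration-dependent effects: 1.0 plays the
    role of a high-expression strain, ~0.4 a strain expressing dCas9
    2.6-fold lower.  The bad-seed component scales linearly with the level;
    the off-target component scales with ``level**offtarget_dose_exponent``
    (a weaker dependence).  ``generations`` documents the length of the
    growth competition the planted log2FC values aggregate over.
    """

    genome_length: int = 50_000
    n_genes: int = 30
    operon_size_probs: tuple = (0.4, 0.35, 0.25)  # P(operon has 1, 2, 3 genes)
    frac_essential: float = 0.30
    frac_fitness: float = 0.10
    promoter_len: int = 100
    gene_length: tuple = (700, 1200)
    intergenic_gap: tuple = (250, 450)
    essential_effect: tuple = (8.0, 0.7)   # mean, sd of -log2FC for essential genes
    fitness_effect: tuple = (5.0, 1.0)
    library_size: int = 8000
    dcas9_level: float = 1.0
    n_bad_seeds: int = 20
    guides_per_bad_seed: int = 45
    bad_seed_tau: tuple = (4.0, 1.0)       # tau_s ~ -|Normal(mean, sd)|
    bad_seed_tau_cap: float = -3.0         # clipped to be at most this strong a ceiling
    offtarget_k: int = 9
    n_offtarget_guides: int = 100
    offtarget_effect_scale: float = 0.65
    offtarget_dose_exponent: float = 0.5
    weak_polar_effect: float = -0.5
    polar_window: int = 100
    generations: int = 17
    replicates: int = 3
    depth_per_guide: int = 500
    nb_dispersion: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("genome_length", "promoter_len", "library_size", "generations",
                     "replicates", "depth_per_guide"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_genes", "n_bad_seeds", "n_offtarget_guides"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("frac_essential", "frac_fitness"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_essential + self.frac_fitness > 1.0:
            raise ValueError("frac_essential + frac_fitness exceeds 1")
        if self.dcas9_level < 0:
            raise ValueError("dcas9_level must be non-negative")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if not 1 <= self.offtarget_k <= 20:
            raise ValueError("offtarget_k must be in [1, 20]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for f in dataclasses.fields(cls):
            if f.name in kwargs and isinstance(getattr(cls, f.name, None), tuple):
                kwargs[f.name] = tuple(kwargs[f.name])
        return cls(**kwargs)


@dataclass
class PlantedDesign:
    """Ledger of everything stamped into the genome at assembly time."""

    bad_seed_tau: dict[str, float]
    badseed_sites: list[tuple[int, str]]
    host_sites: list[tuple[int, str]]
    offtarget_sites: list[dict]
    gene_effects: dict[str, float]


@dataclass
class SimulationTruth:
    """Planted per-guide effect decomposition, in log2FC units.

    ``effects`` has one row per guide with columns effect_on_target,
    effect_polar, effect_offtarget, effect_badseed, effect_total; the polar
    column includes the weak reverse-polar contribution.
    """

    effects: pd.DataFrame
    bad_seed_tau: dict[str, float]
    offtarget_hits: dict[str, list[tuple[int, str]]]
    config: SimulationConfig

    def planted_seed_n(self) -> pd.Series:
        """Number of library guides carrying each planted bad seed."""
        seeds = self.effects["seed5"]
        return seeds[seeds.isin(self.bad_seed_tau)].value_counts()


@dataclass
class SimulationResult:
    genome: GenomeRecord
    annotations: list[GeneAnnotation]
    design: PlantedDesign
    guides: pd.DataFrame
    truth: SimulationTruth
    counts: "CountTable"
    config: SimulationConfig


# ---------------------------------------------------------------------------
# genome assembly


def _place_operons(config: SimulationConfig, rng) -> tuple[list[GeneAnnotation], dict]:
    anns: list[GeneAnnotation] = []
    gene_effects: dict[str, float] = {}
    sizes = np.arange(1, len(config.operon_size_probs) + 1)
    cursor = int(rng.integers(300, 600))
    placed, op_i = 0, 0
    while placed < config.n_genes:
        k = int(rng.choice(sizes, p=config.operon_size_probs))
        k = min(k, config.n_genes - placed)
        lens = rng.integers(config.gene_length[0], config.gene_length[1] + 1, size=k)
        strand = "+" if rng.random() < 0.5 else "-"
        span = config.promoter_len + int(lens.sum()) + 20 * (k - 1)
        if cursor + span > config.genome_length - 300:
            raise ValueError(
                f"genome too short: placed {placed}/{config.n_genes} genes "
                f"in {config.genome_length} nt"
            )
        op_name = f"op{op_i:03d}"
        if strand == "+":
            prom = (cursor, cursor + config.promoter_len)
            g_cursor = prom[1]
            order = range(k)
        else:
            prom = (cursor + span - config.promoter_len, cursor + span)
            g_cursor = prom[0]
            order = range(k)
        for j in order:
            length = int(lens[j])
            if strand == "+":
                start, end = g_cursor, g_cursor + length
                g_cursor = end + 20
            else:
                start, end = g_cursor - length, g_cursor
                g_cursor = start - 20
            name = f"gene{placed:03d}"
            u = rng.random()
            if u < config.frac_essential:
                ess = "essential"
                eff = -abs(rng.normal(*config.essential_effect))
            elif u < config.frac_essential + config.frac_fitness:
                ess = "fitness"
                eff = -abs(rng.normal(*config.fitness_effect))
            else:
                ess = "neutral"
                eff = 0.0
            anns.append(GeneAnnotation(
                gene=name, start=start, end=end, strand=strand,
                essentiality=ess, operon=op_name,
                promoter=prom if j == 0 else None,
            ))
            gene_effects[name] = eff
            placed += 1
        cursor += span + int(rng.integers(*config.intergenic_gap))
        op_i += 1
    return sorted(anns, key=lambda a: a.start), gene_effects


def _random_5mers(rng, n: int, exclude: set[str]) -> list[str]:
    out: list[str] = []
    while len(out) < n:
        s = "".join("ACGT"[i] for i in rng.integers(0, 4, size=5))
        if s not in exclude and s not in out:
            out.append(s)
    return out


class _Stamper:
    """Mutable genome sequence with a reservation mask for planted motifs."""

    def __init__(self, seq: np.ndarray):
        self.seq = seq
        self.reserved = np.zeros(len(seq), dtype=bool)

    def free(self, lo: int, hi: int) -> bool:
        return 0 <= lo and hi <= len(self.seq) and not self.reserved[lo:hi].any()

    def write(self, pos: int, motif: str, reserve: tuple[int, int]):
        enc = np.frombuffer(motif.encode(), dtype=np.uint8)
        self.seq[pos:pos + len(enc)] = enc
        self.reserved[reserve[0]:reserve[1]] = True

    def text(self) -> str:
        return self.seq.tobytes().decode()


def _intergenic_mask(length: int, annotations) -> np.ndarray:
    mask = np.ones(length, dtype=bool)
    for a in annotations:
        mask[a.start:a.end] = False
        if a.promoter:
            mask[a.promoter[0]:a.promoter[1]] = False
    return mask


def generate_genome(config: SimulationConfig, rng):
    """Assemble a random genome with planted motifs.

    Returns ``(GenomeRecord, annotations, PlantedDesign)``.  The sequence is
    i.i.d. uniform ACGT except for (a) stamped bad-seed motifs
    (``seed5 + CGG``) at intergenic positions, (b) planted off-target pairs
    (a template-strand host guide in a neutral gene plus a matching
    ``offtarget_k``-mer + NGG inside an important region), and (c) extra GG
    dinucleotides stamped until the genome carries enough extractable PAM
    sites for the requested library size.
    """
    seq = rng.choice(_BASES, size=config.genome_length).astype(np.uint8)
    annotations, gene_effects = _place_operons(config, rng) if config.n_genes else ([], {})
    st = _Stamper(seq)
    L = config.genome_length

    # --- bad seeds stamped in intergenic space -----------------------------
    control_seed = CONTROL_SPACER[-5:]
    bad_seeds = _random_5mers(rng, config.n_bad_seeds, exclude={control_seed})
    taus = -np.abs(rng.normal(config.bad_seed_tau[0], config.bad_seed_tau[1],
                              size=config.n_bad_seeds))
    taus = np.minimum(taus, config.bad_seed_tau_cap)
    bad_seed_tau = dict(zip(bad_seeds, taus.tolist()))

    inter = _intergenic_mask(L, annotations)
    # keep stamped guides clear of reverse-polar windows downstream of
    # important genes on the forward strand (stamps are forward-strand sites)
    for a in annotations:
        if a.important and a.strand == "+":
            inter[a.end:a.end + 2 * config.polar_window] = False
    candidates = np.nonzero(inter)[0]
    candidates = candidates[(candidates >= 25) & (candidates <= L - 10)]
    candidates = rng.permutation(candidates)

    badseed_sites: list[tuple[int, str]] = []
    ci = 0
    for seed in bad_seeds:
        placed = 0
        while placed < config.guides_per_bad_seed and ci < len(candidates):
            q = int(candidates[ci]); ci += 1
            if not st.free(q, q + 8):
                continue
            st.write(q, seed + "CGG", (q, q + 8))
            badseed_sites.append((q + 5, "+"))
            placed += 1
        if placed < config.guides_per_bad_seed:
            logger.warning("bad seed %s: only %d/%d sites placed",
                           seed, placed, config.guides_per_bad_seed)

    # --- planted off-target pairs ------------------------------------------
    host_sites: list[tuple[int, str]] = []
    offtarget_sites: list[dict] = []
    neutral_genes = [a for a in annotations if a.essentiality == "neutral"
                     and a.length >= 150]
    # planted sites go into essential genes: a partially silenced essential
    # gene still produces a strong defect, a fitness gene may not
    important_genes = [a for a in annotations
                       if a.essentiality == "essential" and a.length >= 120]
    k = config.offtarget_k
    if config.n_offtarget_guides and (not neutral_genes or not important_genes):
        raise ValueError("cannot plant off-targets without neutral and important genes")
    attempts = 0
    while len(host_sites) < config.n_offtarget_guides and attempts < 50 * max(1, config.n_offtarget_guides):
        attempts += 1
        g = neutral_genes[int(rng.integers(len(neutral_genes)))]
        p = int(rng.integers(g.start + 30, g.end - 30))
        host_strand = "-" if g.strand == "+" else "+"
        if host_strand == "-":
            lo, hi = p - 2, p + 21
        else:
            lo, hi = p - 20, p + 3
        if not st.free(lo, hi):
            continue
        # stamp the host PAM; the spacer itself is whatever the genome holds
        if host_strand == "-":
            st.write(p - 2, "CC", (lo, hi))
            host9 = revcomp(st.text()[p + 1:p + 1 + k])
            host10 = revcomp(st.text()[p + 1 + k])  # next PAM-distal base
        else:
            st.write(p + 1, "GG", (lo, hi))
            host9 = st.text()[p - k:p]
            host10 = st.text()[p - k - 1]
        # off-target site on the sense strand of an important gene
        site = None
        for _ in range(40):
            e = important_genes[int(rng.integers(len(important_genes)))]
            m = int(rng.integers(e.start + 30, e.end - 30))
            if e.strand == "+":
                slo, shi = m - k - 1, m + 3
                if st.free(slo, shi):
                    site = (e, m, "+", slo, shi)
                    break
            else:
                slo, shi = m - 2, m + k + 2
                if st.free(slo, shi):
                    site = (e, m, "-", slo, shi)
                    break
        if site is None:
            continue
        e, m, s_strand, slo, shi = site
        alt = {"A": "C", "C": "A", "G": "T", "T": "G"}
        if s_strand == "+":
            st.write(m - k, host9, (slo, shi))
            st.write(m + 1, "GG", (slo, shi))
            if st.text()[m - k - 1] == host10:  # force a mismatch at k+1
                st.write(m - k - 1, alt[host10], (slo, shi))
        else:
            st.write(m + 1, revcomp(host9), (slo, shi))
            st.write(m - 2, "CC", (slo, shi))
            if st.text()[m + k + 1] == revcomp(host10):
                st.write(m + k + 1, alt[revcomp(host10)], (slo, shi))
        host_sites.append((p, host_strand))
        offtarget_sites.append({
            "host": (p, host_strand), "site": (m, s_strand),
            "gene": e.gene, "kmer": host9,
        })
    if len(host_sites) < config.n_offtarget_guides:
        logger.warning("planted only %d/%d off-target pairs",
                       len(host_sites), config.n_offtarget_guides)

    # --- PAM boosters: guarantee enough extractable sites -------------------
    def n_extractable() -> int:
        genome = GenomeRecord("sim", st.text())
        n = 0
        for pam, strand in scan_pams(genome):
            if strand == "+" and pam >= 20:
                n += 1
            elif strand == "-" and pam + 21 <= L:
                n += 1
        return n

    target = config.library_size + 50
    for _ in range(40):
        have = n_extractable()
        if have >= target:
            break
        deficit = target - have
        spots = rng.integers(25, L - 25, size=2 * deficit)
        stamped = 0
        for j in spots:
            j = int(j)
            if stamped >= deficit:
                break
            if st.free(j, j + 2):
                st.write(j, "GG", (j, j + 2))
                stamped += 1
    else:
        raise ValueError("could not reach the requested library size with PAM boosters")

    genome = GenomeRecord("sim_genome", st.text())
    design = PlantedDesign(bad_seed_tau=bad_seed_tau, badseed_sites=badseed_sites,
                           host_sites=host_sites, offtarget_sites=offtarget_sites,
                           gene_effects=gene_effects)
    return genome, annotations, design


def build_library(genome: GenomeRecord, annotations, design: PlantedDesign,
                  config: SimulationConfig, rng) -> pd.DataFrame:
    """Select the guide library: all planted sites plus a random fill.

    Appends the non-targeting control guide used for normalization.
    """
    guides = annotate_guides(extract_guides(genome), annotations)
    mandatory = set(design.badseed_sites) | set(design.host_sites)
    key = list(zip(guides["pam_pos"], guides["strand"]))
    is_mand = np.array([kk in mandatory for kk in key])
    n_fill = config.library_size - int(is_mand.sum())
    if n_fill < 0:
        raise ValueError("library_size smaller than the number of planted guides")
    pool = np.nonzero(~is_mand)[0]
    if len(pool) < n_fill:
        raise ValueError(
            f"only {len(pool) + int(is_mand.sum())} extractable guides for a "
            f"library of {config.library_size}"
        )
    chosen = np.concatenate([np.nonzero(is_mand)[0],
                             rng.choice(pool, size=n_fill, replace=False)])
    lib = guides.iloc[np.sort(chosen)].reset_index(drop=True)
    lib["guide_id"] = [f"g{i:05d}" for i in range(len(lib))]
    lib = pd.concat([lib, pd.DataFrame([control_guide_row()])], ignore_index=True)
    return lib


# ---------------------------------------------------------------------------
# true fitness


def _operon_tables(annotations, gene_effects):
    """Per-gene cumulative silencing effect when elongation is blocked there.

    Blocking gene g silences g and every downstream gene of its operon; the
    aggregate fitness cost is the strongest (most negative) effect among the
    silenced genes.  Promoter silencing covers the whole operon.
    """
    by_op: dict[str, list] = {}
    for a in annotations:
        by_op.setdefault(a.operon, []).append(a)
    block_effect: dict[str, float] = {}
    operon_effect: dict[str, float] = {}
    for op, genes in by_op.items():
        genes = sorted(genes, key=lambda a: a.start, reverse=genes[0].strand == "-")
        effs = [gene_effects[g.gene] for g in genes]
        operon_effect[op] = min(effs) if effs else 0.0
        for i, g in enumerate(genes):
            block_effect[g.gene] = min(effs[i:])
    return block_effect, operon_effect


def terminal_important_genes(annotations) -> list[GeneAnnotation]:
    """Essential/fitness genes not followed by another essential/fitness gene.

    "Followed" means the nearest gene downstream of the 3' end in the gene's
    own orientation, regardless of operon membership.
    """
    anns = sorted(annotations, key=lambda a: a.start)
    out = []
    for i, a in enumerate(anns):
        if not a.important:
            continue
        nxt = None
        if a.strand == "+":
            for b in anns[i + 1:]:
                if b.start >= a.end:
                    nxt = b
                    break
        else:
            for b in reversed(anns[:i]):
                if b.end <= a.start:
                    nxt = b
                    break
        if nxt is None or not nxt.important:
            out.append(a)
    return out


def simulate_true_fitness(guides: pd.DataFrame, annotations, config: SimulationConfig,
                          rng, genome: GenomeRecord, design: PlantedDesign,
                          seed_index: SeedIndex | None = None) -> SimulationTruth:
    """Compose the planted per-guide effect ledger.

    Components (all log2FC units, each <= 0):

    * on-target — coding-orientation guides in essential/fitness gene bodies
      get their gene's effect; promoter guides (either orientation) get the
      strongest effect in the operon;
    * polar — extra depletion when downstream operon genes are more essential
      than the target, plus the weak reverse-polar effect for guides on the
      coding strand within ``polar_window`` nt past the stop of a terminal
      important gene;
    * off-target — guides whose ``offtarget_k`` PAM-proximal bases + NGG
      match inside an important region (scaled by
      ``dcas9_level**offtarget_dose_exponent``);
    * bad seed — tau(seed5) * dcas9_level.
    """
    gene_by_name = {a.gene: a for a in annotations}
    block_effect, operon_effect = _operon_tables(annotations, design.gene_effects)
    terminals = [a for a in terminal_important_genes(annotations)]
    classifier = build_important_classifier(annotations, design.gene_effects)
    if seed_index is None:
        seed_index = index_genome_seeds(genome, config.offtarget_k)

    ot_scale = config.dcas9_level ** config.offtarget_dose_exponent if config.dcas9_level > 0 else 0.0
    rows = []
    offtarget_hits: dict[str, list[tuple[int, str]]] = {}
    for row in guides.itertuples(index=False):
        on = polar = ot = bs = 0.0
        if not row.is_control:
            if row.orientation == "coding" and row.target_gene in gene_by_name:
                own = design.gene_effects.get(row.target_gene, 0.0)
                full = block_effect.get(row.target_gene, own)
                on = own
                polar = full - own
            elif row.orientation == "promoter" and row.target_gene in gene_by_name:
                on = operon_effect.get(gene_by_name[row.target_gene].operon, 0.0)
            # weak reverse-polar window past terminal important genes
            pos = pam_proximal_base(row.pam_pos, row.strand)
            for t in terminals:
                if row.strand != t.strand:
                    continue
                d = pos - t.end if t.strand == "+" else t.start - 1 - pos
                if 0 <= d < config.polar_window:
                    polar += config.weak_polar_effect
                    break
            # off-target component
            hits = []
            for site_pam, site_strand in seed_index.sites.get(row.spacer[-seed_index.k:], ()):
                if (site_pam, site_strand) == (row.pam_pos, row.strand):
                    continue
                imp, eff = classifier(site_pam, site_strand)
                if imp:
                    hits.append(((site_pam, site_strand), eff))
            if hits:
                # partial silencing: seed-only binding represses the
                # implicated genes far less than full on-target occupancy
                ot = config.offtarget_effect_scale * min(e for _, e in hits) * ot_scale
                offtarget_hits[row.guide_id] = [h for h, _ in hits]
            bs = design.bad_seed_tau.get(row.seed5, 0.0) * config.dcas9_level
        rows.append((row.guide_id, row.seed5, on, polar, ot, bs, on + polar + ot + bs))

    effects = pd.DataFrame(rows, columns=[
        "guide_id", "seed5", "effect_on_target", "effect_polar",
        "effect_offtarget", "effect_badseed", "effect_total",
    ]).set_index("guide_id")
    return SimulationTruth(effects=effects, bad_seed_tau=design.bad_seed_tau,
                           offtarget_hits=offtarget_hits, config=config)


# ---------------------------------------------------------------------------
# sequencing counts


def simulate_counts(truth: SimulationTruth, config: SimulationConfig, rng,
                    spacers: pd.Series | None = None) -> "CountTable":
    """Draw negative-binomial read counts for start/end timepoints.

    One Dirichlet(1) start-abundance vector is shared across replicates; the
    end abundance of guide g is proportional to ``start_g * 2**effect_g``.
    Counts are NB with mean ``share * depth`` and dispersion
    ``nb_dispersion`` (variance mu + alpha*mu^2), independent per replicate
    and timepoint.
    """
    from .foldchange import CountTable

    effects = truth.effects["effect_total"].to_numpy()
    n = len(effects)
    start_share = rng.dirichlet(np.ones(n))
    # the normalization anchor must be a typically abundant library member;
    # an exchangeable draw can leave it with a handful of reads
    is_ctrl = truth.effects.index == "control"
    if is_ctrl.any():
        start_share[is_ctrl] = 1.0 / n
        start_share = start_share / start_share.sum()
    end_unnorm = start_share * np.exp2(effects)
    end_share = end_unnorm / end_unnorm.sum()
    depth = config.depth_per_guide * n

    cols, data = [], []
    for r in range(1, config.replicates + 1):
        for tp, share in (("start", start_share), ("end", end_share)):
            mu = share * depth
            if config.nb_dispersion > 0:
                lam = rng.gamma(1.0 / config.nb_dispersion, mu * config.nb_dispersion)
                counts = rng.poisson(lam)
            else:
                counts = rng.poisson(mu)
            cols.append(f"{tp}_{r}")
            data.append(counts)
    frame = pd.DataFrame(dict(zip(cols, data)), index=truth.effects.index)
    frame.index.name = "guide_id"
    return CountTable(counts=frame, spacers=spacers)


def simulate_screen(config: SimulationConfig | None = None, seed: int | None = None) -> SimulationResult:
    """Run the full generator: genome, library, truth ledger, counts."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    genome, annotations, design = generate_genome(config, rng)
    guides = build_library(genome, annotations, design, config, rng)
    truth = simulate_true_fitness(guides, annotations, config, rng, genome, design)
    spacers = guides.set_index("guide_id")["spacer"]
    counts = simulate_counts(truth, config, rng, spacers=spacers)
    return SimulationResult(genome=genome, annotations=annotations, design=design,
                            guides=guides, truth=truth, counts=counts, config=config)


def write_run(result: SimulationResult, out_dir, config_hash: str = ""):
    """Emit all simulation artifacts (FASTA, TSVs, truth ledger, config)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hdr = [f"config_hash={config_hash}"] if config_hash else []
    write_genome_fasta(result.genome, out / "genome.fasta",
                       description=f"config_hash={config_hash}")
    write_annotation_tsv(result.annotations, out / "annotation.tsv", header_lines=hdr)
    write_guides_tsv(result.guides, out / "guides.tsv", header_lines=hdr)
    from .foldchange import write_counts_tsv
    write_counts_tsv(result.counts, out / "counts.tsv", header_lines=hdr)
    with open(out / "truth.tsv", "w") as fh:
        for line in hdr:
            fh.write(f"# {line}\n")
        result.truth.effects.to_csv(fh, sep="\t")
    ledger = {
        "config_hash": config_hash,
        "bad_seed_tau": result.truth.bad_seed_tau,
        "offtarget_hits": {g: [[p, s] for p, s in hits]
                           for g, hits in result.truth.offtarget_hits.items()},
        "gene_effects": result.design.gene_effects,
    }
    (out / "truth.json").write_text(json.dumps(ledger, indent=1, sort_keys=True))
    cfg = result.config.to_dict()
    cfg["config_hash"] = config_hash
    (out / "sim_config.json").write_text(json.dumps(cfg, indent=1, sort_keys=True))
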