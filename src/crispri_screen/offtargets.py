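"""Seed-match off-target discovery and the detection-rate sweep.

Off-target candidacy is defined by perfect identity of the k PAM-proximal
bases between a guide's spacer and another NGG site, extended base-by-base
outward from the PAM to the maximal match length (no gaps; mismatches beyond
the matched prefix are ignored).  A hit matters when it falls in an
"important region": the coding strand of a gene whose block silences an
essential/fitness gene (the gene itself or a downstream operon member), or
the promoter of such an operon in either orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeRecord, pam_proximal_base, scan_pams

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SeedIndex:
    """k-mer index over all NGG sites of a genome.

    ``sites[kmer]`` lists the ``(pam_pos, strand)`` sites whose k
    PAM-proximal protospacer bases equal ``kmer``.
    """

    k: int
    sites: dict[str, list[tuple[int, str]]]
    genome: GenomeRecord

    def __len__(self) -> int:
        return sum(len(v) for v in self.sites.values())


@dataclass
class OffTargetHit:
    guide_id: str
    pam_pos: int
    strand: str
    match_len: int
    feature: str | None
    feature_orientation: str
    in_important_region: bool


@dataclass
class DetectionCurve:
    """Detection rates per seed-match length k.

    ``frame`` has columns k, positive_rate, false_positive_rate, difference;
    ``argmax_k`` is the k maximizing the difference.
    """

    frame: pd.DataFrame
    argmax_k: int
    n_defect: int
    n_no_defect: int


def index_genome_seeds(genome: GenomeRecord, k: int) -> SeedIndex:
    """Index every NGG site by its k PAM-proximal bases (both strands)."""
    if not 1 <= k <= 20:
        raise ValueError("k must be in [1, 20]")
    seq = genome.sequence
    L = len(seq)
    sites: dict[str, list[tuple[int, str]]] = {}
    for pam, strand in scan_pams(genome):
        if strand == "+":
            if pam >= k:
                kmer = seq[pam - k:pam]
            elif genome.circular:
                kmer = (seq + seq)[(pam - k) % L:(pam - k) % L + k]
            else:
                continue
        else:
            if pam + 1 + k <= L:
                kmer = _revcomp(seq[pam + 1:pam + 1 + k])
            elif genome.circular:
                kmer = _revcomp((seq + seq)[pam + 1:pam + 1 + k])
            else:
                continue
        sites.setdefault(kmer, []).append((pam, strand))
    return SeedIndex(k=k, sites=sites, genome=genome)


def _revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def match_length(genome: GenomeRecord, spacer: str, pam_pos: int, strand: str,
                 max_len: int = 20) -> int:
    """Maximal PAM-proximal identity between a spacer and a genomic site."""
    seq, L = genome.sequence, len(genome)
    n = 0
    for t in range(max_len):
        if strand == "+":
            g = pam_pos - 1 - t
            if g < 0:
                if not genome.circular:
                    break
                g %= L
            base = seq[g]
        else:
            g = pam_pos + 1 + t
            if g >= L:
                if not genome.circular:
                    break
                g %= L
            base = _COMP[seq[g]]
        if base != spacer[len(spacer) - 1 - t]:
            break
        n += 1
    return n


def build_important_classifier(annotations, gene_effects: dict | None = None
                               ) -> Callable[[int, str], tuple[bool, float]]:
    """Predicate mapping a site ``(pam_pos, strand)`` to important-region
    membership, with the implicated silencing effect when effects are known.

    Membership follows the repression geometry of dCas9: gene bodies count
    only for sites on the gene's sense strand (coding orientation), and only
    when blocking there silences an essential/fitness gene (the gene itself
    or a downstream member of its operon); operon promoters of such genes
    count in both orientations.  With ``gene_effects`` unknown the implicated
    effect is reported as -1.0 (membership is all the analyses use).
    """
    by_op: dict[str, list] = {}
    for a in annotations:
        by_op.setdefault(a.operon, []).append(a)

    def eff(gene) -> float:
        if gene_effects is not None:
            return gene_effects.get(gene, 0.0)
        return 0.0

    block_imp: list[tuple[int, int, str, bool, float]] = []  # gene bodies
    prom_imp: list[tuple[int, int, bool, float]] = []        # promoters
    for op, genes in by_op.items():
        genes = sorted(genes, key=lambda a: a.start, reverse=genes[0].strand == "-")
        down_imp = [g.important for g in genes]
        for i, g in enumerate(genes):
            silences = any(down_imp[i:])
            if gene_effects is not None:
                e = min((eff(h.gene) for h in genes[i:]), default=0.0)
            else:
                e = -1.0 if silences else 0.0
            block_imp.append((g.start, g.end, g.strand, silences, e))
        op_imp = any(down_imp)
        op_eff = min((eff(h.gene) for h in genes), default=0.0) if gene_effects is not None \
            else (-1.0 if op_imp else 0.0)
        for g in genes:
            if g.promoter:
                prom_imp.append((g.promoter[0], g.promoter[1], op_imp, op_eff))

    def classify(pam_pos: int, strand: str) -> tuple[bool, float]:
        for lo, hi, imp, e in prom_imp:
            if lo <= pam_pos < hi:
                return (imp, e) if imp else (False, 0.0)
        pos = pam_proximal_base(pam_pos, strand)
        for lo, hi, g_strand, imp, e in block_imp:
            if lo <= pos < hi and strand == g_strand and imp:
                return True, e
        return False, 0.0

    return classify


def _orientation_blind_classifier(annotations) -> Callable[[int, str], tuple[bool, float]]:
    """Simpler membership rule ignoring strand (config alternative)."""
    base = build_important_classifier(annotations)

    def classify(pam_pos: int, strand: str) -> tuple[bool, float]:
        a = base(pam_pos, "+")
        b = base(pam_pos, "-")
        return (a[0] or b[0], min(a[1], b[1]))

    return classify


def find_offtargets(guide, index: SeedIndex, min_k: int = 9,
                    classifier: Callable[[int, str], tuple[bool, float]] | None = None,
                    annotations: Sequence | None = None) -> list[OffTargetHit]:
    """All off-target sites of one guide with PAM-proximal identity >= min_k.

    ``guide`` is a mapping/namedtuple with spacer, pam_pos, strand, guide_id.
    The guide's own site is excluded.  ``min_k`` must be at least the index
    k; candidates are looked up by their ``index.k``-mer and extended to the
    maximal match length.
    """
    if min_k < index.k:
        raise ValueError(f"min_k={min_k} below index k={index.k}")
    spacer = guide["spacer"] if isinstance(guide, dict) else guide.spacer
    pam_pos = guide["pam_pos"] if isinstance(guide, dict) else guide.pam_pos
    strand = guide["strand"] if isinstance(guide, dict) else guide.strand
    guide_id = guide["guide_id"] if isinstance(guide, dict) else guide.guide_id

    if classifier is None:
        if annotations is not None:
            classifier = build_important_classifier(annotations)
        else:
            classifier = lambda p, s: (False, 0.0)
    gene_lookup = None
    if annotations is not None:
        gene_lookup = sorted(annotations, key=lambda a: a.start)

    hits = []
    for site_pam, site_strand in index.sites.get(spacer[-index.k:], ()):
        if (site_pam, site_strand) == (pam_pos, strand):
            continue
        mlen = match_length(index.genome, spacer, site_pam, site_strand)
        if mlen < min_k:
            continue
        feature, feat_orient = None, "intergenic"
        if gene_lookup is not None:
            pos = pam_proximal_base(site_pam, site_strand)
            for a in gene_lookup:
                if a.promoter and a.promoter[0] <= site_pam < a.promoter[1]:
                    feature, feat_orient = a.gene, "promoter"
                    break
                if a.start <= pos < a.end:
                    feature = a.gene
                    feat_orient = "coding" if site_strand == a.strand else "template"
                    break
        imp, _ = classifier(site_pam, site_strand)
        hits.append(OffTargetHit(guide_id=guide_id, pam_pos=site_pam,
                                 strand=site_strand, match_len=mlen,
                                 feature=feature, feature_orientation=feat_orient,
                                 in_important_region=imp))
    hits.sort(key=lambda h: (h.pam_pos, h.strand))
    return hits


def best_important_match(guides: pd.DataFrame, index: SeedIndex,
                         classifier) -> pd.Series:
    """Per guide, the maximal match length over important-region off-targets
    (0 when none)."""
    out = {}
    for row in guides.itertuples(index=False):
        best = 0
        for site_pam, site_strand in index.sites.get(row.spacer[-index.k:], ()):
            if (site_pam, site_strand) == (row.pam_pos, row.strand):
                continue
            if not classifier(site_pam, site_strand)[0]:
                continue
            best = max(best, match_length(index.genome, row.spacer,
                                          site_pam, site_strand))
        out[row.guide_id] = best
    return pd.Series(out, name="best_important_match")


def detection_rate_curve(defect_guides: pd.DataFrame, no_defect_guides: pd.DataFrame,
                         index: SeedIndex, classifier,
                         k_range: Iterable[int] = range(6, 16)) -> DetectionCurve:
    """Fraction of each guide set with an important-region off-target at
    match length >= k, for k over ``k_range``.

    The positive set holds guides with an unexpected strong fitness defect,
    the control set guides in the same genes/orientation without a defect;
    the difference curve estimates the fraction of defects explained by
    off-targets, and its argmax the minimal identity that silences.
    """
    if len(defect_guides) == 0 or len(no_defect_guides) == 0:
        raise ValueError("both guide sets must be non-empty")
    ks = list(k_range)
    if min(ks) < index.k:
        raise ValueError("k_range extends below the index k")
    best_pos = best_important_match(defect_guides, index, classifier).to_numpy()
    best_neg = best_important_match(no_defect_guides, index, classifier).to_numpy()
    rows = []
    for k in ks:
        p = float(np.mean(best_pos >= k))
        f = float(np.mean(best_neg >= k))
        rows.append((k, p, f, p - f))
    frame = pd.DataFrame(rows, columns=["k", "positive_rate",
                                        "false_positive_rate", "difference"])
    argmax_k = int(frame.loc[frame["difference"].idxmax(), "k"])
    return DetectionCurve(frame=frame, argmax_k=argmax_k,
                          n_defect=len(defect_guides),
                          n_no_defect=len(no_defect_guides))


def offtarget_fisher_test(best_defect: np.ndarray, best_no_defect: np.ndarray,
                          k: int = 9) -> tuple[float, float]:
    """Fisher exact test of the defect/no-defect x hit/no-hit table at k."""
    table = [
        [int(np.sum(best_defect >= k)), int(np.sum(best_defect < k))],
        [int(np.sum(best_no_defect >= k)), int(np.sum(best_no_defect < k))],
    ]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def hits_to_frame(hits: Sequence[OffTargetHit]) -> pd.DataFrame:
    return pd.DataFrame([h.__dict__ for h in hits],
                        columns=["guide_id", "pam_pos", "strand", "match_len",
                                 "feature", "feature_orientation",
                                 "in_important_region"])


def write_hits_bed(hits: Sequence[OffTargetHit], genome_id: str, path):
    with open(path, "w") as fh:
        for h in hits:
            lo = h.pam_pos if h.strand == "+" else h.pam_pos - 2
            fh.write(f"{genome_id}\t{lo}\t{lo + 3}\t{h.guide_id}|k={h.match_len}"
                     f"\t{int(h.in_important_region)}\t{h.strand}\n")
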