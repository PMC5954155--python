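"""Genome, annotation and guide handling for bacterial CRISPRi screens.

Conventions used throughout the package:

* coordinates are 0-based, half-open, on the forward strand;
* a PAM site is identified by ``(pam_pos, strand)`` where ``pam_pos`` is the
  forward-strand coordinate of the *first* base of the NGG trinucleotide as
  read on the strand carrying the protospacer;
* the spacer is the 20 nt immediately 5' of the PAM on the protospacer strand,
  and ``seed5`` is its 5 PAM-proximal bases (``spacer[15:20]``);
* ``orientation`` is "coding" when the protospacer (and PAM) lie on the target
  gene's sense strand — the geometry in which dCas9 blocks transcription
  elongation — and "template" otherwise.  Guides whose PAM falls in an
  annotated promoter are labelled "promoter"; guides outside genes and
  promoters are "intergenic".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

SPACER_LEN = 20
SEED_LEN = 5
#: Non-targeting control guide used to anchor fold-change normalization.
CONTROL_SPACER = "TGAGACCAGTCTAGGTCTCG"

ESSENTIALITY_CLASSES = ("essential", "fitness", "neutral")
ORIENTATIONS = ("coding", "template", "promoter", "intergenic")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Column order of the canonical guide table written by :func:`write_guides_tsv`.
GUIDE_COLUMNS = [
    "guide_id", "spacer", "pam_pos", "strand", "seed5", "target_gene",
    "orientation", "dist_from_start", "dist_from_end", "rel_pos",
    "multi_mapping", "is_control",
]


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """A single replicon: identifier, ACGT sequence, topology."""

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("genome sequence is empty")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(
                f"genome {self.id!r} contains non-ACGT characters {sorted(bad)}; "
                "ambiguous bases (e.g. N) are not supported"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with essentiality class and operon/promoter context.

    ``start``/``end`` are 0-based half-open genomic coordinates; wrapping
    genes on circular genomes are rejected.  ``promoter`` is an optional
    0-based half-open interval (usually attached to the first gene of an
    operon).
    """

    gene: str
    start: int
    end: int
    strand: str
    essentiality: str
    operon: str
    promoter: tuple[int, int] | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene!r}: malformed interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene!r}: strand must be '+' or '-'")
        if self.essentiality not in ESSENTIALITY_CLASSES:
            raise ValueError(
                f"gene {self.gene!r}: unknown essentiality {self.essentiality!r}; "
                f"expected one of {ESSENTIALITY_CLASSES}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def important(self) -> bool:
        """True for genes whose knockdown is expected to cost fitness."""
        return self.essentiality in ("essential", "fitness")


# ---------------------------------------------------------------------------
# I/O


def load_genome(fasta_path, annotation_path, circular: bool = False):
    """Read a genome FASTA plus gene annotation.

    The first FASTA record is used.  The annotation may be the canonical
    7-column TSV (gene, start, end, strand, essentiality, operon, promoter)
    or a GFF3 file (extension .gff/.gff3) whose gene features carry
    ``essentiality``/``operon``/``promoter`` attributes.

    Returns
    -------
    (GenomeRecord, list[GeneAnnotation])
        Annotations sorted by start coordinate.
    """
    fasta_path, annotation_path = Path(fasta_path), Path(annotation_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"{fasta_path}: no FASTA records")
    rec = records[0]
    genome = GenomeRecord(id=rec.id, sequence=str(rec.seq).upper(), circular=circular)

    if annotation_path.suffix.lower() in (".gff", ".gff3"):
        anns = read_annotation_gff3(annotation_path)
    else:
        anns = read_annotation_tsv(annotation_path)
    for a in anns:
        if a.end > len(genome):
            raise ValueError(
                f"gene {a.gene!r}: end {a.end} exceeds genome length {len(genome)}"
            )
    return genome, sorted(anns, key=lambda a: a.start)


def _parse_promoter(field: str) -> tuple[int, int] | None:
    field = str(field).strip()
    if field in ("", ".", "nan", "None"):
        return None
    lo, hi = field.split("-")
    return int(lo), int(hi)


def read_annotation_tsv(path) -> list[GeneAnnotation]:
    """Read the canonical gene-annotation TSV.

    Columns: gene, start, end, strand, essentiality, operon, promoter
    (promoter as ``start-end`` or ``.``).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"gene", "start", "end", "strand", "essentiality", "operon", "promoter"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: annotation TSV missing columns {sorted(missing)}")
    return [
        GeneAnnotation(
            gene=row["gene"], start=int(row["start"]), end=int(row["end"]),
            strand=row["strand"], essentiality=row["essentiality"],
            operon=row["operon"], promoter=_parse_promoter(row["promoter"]),
        )
        for _, row in df.iterrows()
    ]


def write_annotation_tsv(annotations: Sequence[GeneAnnotation], path, header_lines=()):
    rows = []
    for a in annotations:
        prom = f"{a.promoter[0]}-{a.promoter[1]}" if a.promoter else "."
        rows.append((a.gene, a.start, a.end, a.strand, a.essentiality, a.operon, prom))
    df = pd.DataFrame(rows, columns=["gene", "start", "end", "strand",
                                     "essentiality", "operon", "promoter"])
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_annotation_gff3(path) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 (gene features only).

    Essentiality/operon context has no GFF3 standard, so it is carried in the
    attribute column: ``essentiality=...;operon=...`` and optionally
    ``promoter=<start>-<end>`` (1-based inclusive, like GFF coordinates).
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    anns = []
    for feat in db.features_of_type("gene"):
        name = feat.attributes.get("Name", [feat.id])[0]
        if "essentiality" not in feat.attributes:
            raise ValueError(f"gene {name!r}: GFF3 record lacks an 'essentiality' attribute")
        prom = None
        if "promoter" in feat.attributes:
            lo, hi = feat.attributes["promoter"][0].split("-")
            prom = (int(lo) - 1, int(hi))  # 1-based inclusive -> 0-based half-open
        anns.append(GeneAnnotation(
            gene=name,
            start=feat.start - 1, end=feat.end,  # GFF is 1-based inclusive
            strand=feat.strand,
            essentiality=feat.attributes["essentiality"][0],
            operon=feat.attributes.get("operon", [name])[0],
            promoter=prom,
        ))
    return anns


def write_genome_fasta(genome: GenomeRecord, path, description: str = ""):
    with open(path, "w") as fh:
        fh.write(f">{genome.id} {description}\n")
        seq = genome.sequence
        for i in range(0, len(seq), 80):
            fh.write(seq[i:i + 80] + "\n")


# ---------------------------------------------------------------------------
# PAM scanning and guide extraction


def scan_pams(genome: GenomeRecord) -> list[tuple[int, str]]:
    """Enumerate all NGG PAM sites on both strands.

    Forward-strand sites are positions ``i`` with ``sequence[i+1:i+3] == "GG"``;
    reverse-strand sites are positions ``p`` with ``sequence[p-2:p] == "CC"``
    (the NGG read on the reverse strand).  Coordinates are reported on the
    forward strand; circular genomes wrap across the origin.
    """
    seq = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    L = len(seq)
    is_g = seq == ord("G")
    is_c = seq == ord("C")
    sites: list[tuple[int, str]] = []

    if genome.circular:
        g_ext = np.concatenate([is_g, is_g[:2]])
        fwd = np.nonzero(g_ext[1:L + 1] & g_ext[2:L + 2])[0]
        c_ext = np.concatenate([is_c[-2:], is_c])
        rev = np.nonzero(c_ext[0:L] & c_ext[1:L + 1])[0]
    else:
        fwd = np.nonzero(is_g[1:-1] & is_g[2:])[0] if L >= 3 else np.array([], dtype=int)
        rev = 2 + np.nonzero(is_c[:-2] & is_c[1:-1])[0] if L >= 3 else np.array([], dtype=int)

    sites.extend((int(i), "+") for i in fwd)
    sites.extend((int(p), "-") for p in rev)
    sites.sort()
    return sites


def spacer_at(genome: GenomeRecord, pam_pos: int, strand: str) -> str | None:
    """The 20-nt spacer 5' of the PAM at a site, or None if the flank is short.

    On circular genomes the spacer wraps across the origin.
    """
    seq, L = genome.sequence, len(genome)
    if strand == "+":
        if pam_pos >= SPACER_LEN:
            return seq[pam_pos - SPACER_LEN:pam_pos]
        if genome.circular:
            start = (pam_pos - SPACER_LEN) % L
            return (seq + seq)[start:start + SPACER_LEN]
        return None
    if pam_pos + 1 + SPACER_LEN <= L:
        return revcomp(seq[pam_pos + 1:pam_pos + 1 + SPACER_LEN])
    if genome.circular:
        return revcomp((seq + seq)[pam_pos + 1:pam_pos + 1 + SPACER_LEN])
    return None


def pam_proximal_base(pam_pos: int, strand: str) -> int:
    """Forward-strand coordinate of the PAM-proximal spacer base of a site."""
    return pam_pos - 1 if strand == "+" else pam_pos + 1


def extract_guides(genome: GenomeRecord, pam_sites=None) -> pd.DataFrame:
    """Extract 20-nt guides for every PAM site with a sufficient 5' flank.

    Sites on linear genomes lacking 20 nt of protospacer are skipped (counted
    in a log line).  Guides whose spacer occurs at more than one genomic site
    are flagged ``multi_mapping``.

    Returns a DataFrame with :data:`GUIDE_COLUMNS` (annotation columns unset).
    """
    if pam_sites is None:
        pam_sites = scan_pams(genome)
    rows, skipped = [], 0
    for pam_pos, strand in pam_sites:
        spacer = spacer_at(genome, pam_pos, strand)
        if spacer is None:
            skipped += 1
            continue
        rows.append((f"g{pam_pos:08d}{'f' if strand == '+' else 'r'}",
                     spacer, pam_pos, strand, spacer[-SEED_LEN:]))
    if skipped:
        logger.info("extract_guides: skipped %d PAM sites with <%d nt flank",
                    skipped, SPACER_LEN)
    df = pd.DataFrame(rows, columns=["guide_id", "spacer", "pam_pos", "strand", "seed5"])
    df["target_gene"] = None
    df["orientation"] = "intergenic"
    df["dist_from_start"] = np.nan
    df["dist_from_end"] = np.nan
    df["rel_pos"] = np.nan
    df["multi_mapping"] = df["spacer"].duplicated(keep=False)
    df["is_control"] = False
    return df


def annotate_guides(guides: pd.DataFrame, annotations: Sequence[GeneAnnotation]) -> pd.DataFrame:
    """Assign target gene, orientation and within-gene position to guides.

    Orientation: "promoter" if the PAM falls in an annotated promoter
    interval; otherwise "coding"/"template" for guides whose PAM-proximal
    spacer base lies in a gene body, depending on whether the protospacer
    strand matches the gene's sense strand; "intergenic" otherwise.  When
    several gene bodies overlap the guide, the gene whose body contains the
    PAM wins, ties broken by coordinate order (logged).

    Distances are measured from the PAM-proximal spacer base: nt from the
    gene's 5' start (``dist_from_start``), nt from its 3' end
    (``dist_from_end``), and the fraction ``rel_pos`` in [0, 1].
    """
    guides = guides.copy()
    anns = sorted(annotations, key=lambda a: a.start)
    promoters = [(a.promoter[0], a.promoter[1], a) for a in anns if a.promoter]

    tg = [None] * len(guides)
    orient = ["intergenic"] * len(guides)
    d_start = np.full(len(guides), np.nan)
    d_end = np.full(len(guides), np.nan)
    rel = np.full(len(guides), np.nan)

    for k, row in enumerate(guides.itertuples(index=False)):
        if getattr(row, "is_control", False):
            orient[k] = "control"
            continue
        pos = pam_proximal_base(row.pam_pos, row.strand)
        hit = None
        for lo, hi, a in promoters:
            if lo <= row.pam_pos < hi:
                tg[k], orient[k] = a.gene, "promoter"
                hit = a
                break
        if hit is not None:
            continue
        body = [a for a in anns if a.start <= pos < a.end]
        if not body:
            continue
        if len(body) > 1:
            with_pam = [a for a in body if a.start <= row.pam_pos < a.end]
            if with_pam:
                body = with_pam
            if len(body) > 1:
                logger.info("guide %s overlaps genes %s; assigned to %s",
                            row.guide_id, [a.gene for a in body], body[0].gene)
        a = body[0]
        tg[k] = a.gene
        orient[k] = "coding" if row.strand == a.strand else "template"
        ds = pos - a.start if a.strand == "+" else a.end - 1 - pos
        d_start[k] = ds
        d_end[k] = a.length - 1 - ds
        rel[k] = ds / (a.length - 1) if a.length > 1 else 0.0

    guides["target_gene"] = tg
    guides["orientation"] = orient
    guides["dist_from_start"] = d_start
    guides["dist_from_end"] = d_end
    guides["rel_pos"] = rel
    return guides


def control_guide_row(guide_id: str = "control") -> dict:
    """Table row for the non-targeting normalization control guide."""
    return {
        "guide_id": guide_id, "spacer": CONTROL_SPACER, "pam_pos": -1,
        "strand": "+", "seed5": CONTROL_SPACER[-SEED_LEN:], "target_gene": None,
        "orientation": "control", "dist_from_start": np.nan,
        "dist_from_end": np.nan, "rel_pos": np.nan,
        "multi_mapping": False, "is_control": True,
    }


def write_guides_tsv(guides: pd.DataFrame, path, header_lines=()):
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        guides[GUIDE_COLUMNS].to_csv(fh, sep="\t", index=False)


def read_guides_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df["multi_mapping"] = df["multi_mapping"].astype(bool)
    df["is_control"] = df["is_control"].astype(bool)
    return df


def write_pam_bed(pam_sites: Iterable[tuple[int, str]], genome_id: str, path):
    """Export PAM sites as BED (0-based half-open, NGG trinucleotide span)."""
    with open(path, "w") as fh:
        for pam_pos, strand in pam_sites:
            lo = pam_pos if strand == "+" else pam_pos - 2
            fh.write(f"{genome_id}\t{lo}\t{lo + 3}\tNGG\t0\t{strand}\n")
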