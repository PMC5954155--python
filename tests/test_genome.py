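"""Genome I/O, PAM scanning and guide extraction/annotation."""

import re

import pytest
from hypothesis import given, settings, strategies as st

from crispri_screen.genome import (
    CONTROL_SPACER,
    GeneAnnotation,
    GenomeRecord,
    annotate_guides,
    extract_guides,
    load_genome,
    revcomp,
    scan_pams,
    spacer_at,
)


def brute_force_pams(seq: str, circular: bool):
    """Independent oracle: regex scan of the sequence and its reverse
    complement, reverse coordinates mapped back to the forward strand."""
    L = len(seq)
    fwd_text = seq + seq[:2] if circular else seq
    rc = revcomp(seq)
    rc_text = rc + rc[:2] if circular else rc
    sites = set()
    for m in re.finditer(r"(?=[ACGT]GG)", fwd_text):
        if m.start() < L:
            sites.add((m.start(), "+"))
    for m in re.finditer(r"(?=[ACGT]GG)", rc_text):
        if m.start() < L:
            sites.add((L - 1 - m.start(), "-"))
    return sorted(sites)


class TestScanPams:
    def test_no_gg_anywhere(self):
        assert scan_pams(GenomeRecord("g", "AAAAAA")) == []

    def test_single_forward_site(self):
        # exhaustive hand scan of ACGGTT: only CGG at position 1 (+)
        assert scan_pams(GenomeRecord("g", "ACGGTT")) == [(1, "+")]

    def test_reverse_site_coordinates(self):
        # CCA read on the reverse strand is TGG; N base sits at index 2
        assert scan_pams(GenomeRecord("g", "CCAAAA")) == [(2, "-")]

    @pytest.mark.parametrize("circular", [False, True])
    def test_matches_regex_oracle_on_random_sequences(self, circular, rng):
        for _ in range(50):
            L = int(rng.integers(50, 2000))
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=L))
            genome = GenomeRecord("r", seq, circular=circular)
            assert scan_pams(genome) == brute_force_pams(seq, circular)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=3, max_size=200),
           st.booleans())
    def test_oracle_property(self, seq, circular):
        genome = GenomeRecord("h", seq, circular=circular)
        assert scan_pams(genome) == brute_force_pams(seq, circular)

    def test_reverse_complement_mirror_symmetry(self, rng):
        """Scanning the reverse complement yields the coordinate-mirrored,
        strand-swapped PAM set."""
        for _ in range(20):
            L = int(rng.integers(60, 500))
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=L))
            fwd = set(scan_pams(GenomeRecord("f", seq)))
            mir = {(L - 1 - p, {"+": "-", "-": "+"}[s])
                   for p, s in scan_pams(GenomeRecord("r", revcomp(seq)))}
            assert fwd == mir

    def test_circular_wraps_origin(self):
        # GG at the start pairs with an N at the end only on a circle
        lin = GenomeRecord("l", "GGAAAAAA")
        circ = GenomeRecord("c", "GGAAAAAA", circular=True)
        assert (7, "+") not in scan_pams(lin)
        assert (7, "+") in scan_pams(circ)


class TestExtractGuides:
    def test_exact_flank(self):
        seq = "ACGTACGTACGTACGTACGT" + "AGG"
        g = extract_guides(GenomeRecord("g", seq))
        row = g[(g.pam_pos == 20) & (g.strand == "+")].iloc[0]
        assert row.spacer == seq[:20]

    def test_insufficient_flank_skipped(self):
        # PAM at position 5 on a linear genome has <20 nt of spacer
        seq = "AAAAA" + "CGG" + "A" * 10
        g = extract_guides(GenomeRecord("g", seq))
        assert (g.pam_pos == 5).sum() == 0

    def test_circular_flank_wraps(self):
        seq = "CGG" + "A" * 30
        g_circ = extract_guides(GenomeRecord("g", seq, circular=True))
        assert (g_circ.pam_pos == 0).any()

    def test_control_spacer_seed_is_pam_proximal_five(self):
        """The non-targeting control guide carries a TCTCG seed."""
        genome = GenomeRecord("g", "AT" * 5 + CONTROL_SPACER + "AGGTT")
        g = extract_guides(genome)
        row = g[g.spacer == CONTROL_SPACER].iloc[0]
        assert row.seed5 == "TCTCG"
        assert row.seed5 == CONTROL_SPACER[-5:]

    def test_relocation_recovers_sites(self, rng):
        """Searching the genome for spacer+NGG finds exactly the recorded
        (pam_pos, strand)."""
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3000))
        genome = GenomeRecord("g", seq)
        guides = extract_guides(genome)
        sub = guides[~guides.multi_mapping].sample(40, random_state=0)
        for row in sub.itertuples(index=False):
            occurrences = []
            for m in re.finditer(f"(?={row.spacer}[ACGT]GG)", seq):
                occurrences.append((m.start() + 20, "+"))
            for m in re.finditer(f"(?={revcomp(row.spacer)})", seq):
                p = m.start() - 1
                if p >= 2 and seq[p - 2:p] == "CC":
                    occurrences.append((p, "-"))
            assert occurrences == [(row.pam_pos, row.strand)]

    def test_spacer_matches_genome(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=1000))
        genome = GenomeRecord("g", seq)
        for row in extract_guides(genome).itertuples(index=False):
            assert spacer_at(genome, row.pam_pos, row.strand) == row.spacer


class TestAnnotateGuides:
    def test_hand_derived_labels(self, three_gene_genome):
        genome, anns = three_gene_genome
        import pandas as pd

        guides = pd.DataFrame([
            # pam inside geneA on '+' -> protospacer on sense strand: coding
            {"guide_id": "a", "spacer": "A" * 20, "pam_pos": 150, "strand": "+",
             "seed5": "A" * 5},
            # same position, '-' protospacer: template
            {"guide_id": "b", "spacer": "A" * 20, "pam_pos": 150, "strand": "-",
             "seed5": "A" * 5},
            # pam in geneA's promoter
            {"guide_id": "c", "spacer": "A" * 20, "pam_pos": 70, "strand": "-",
             "seed5": "A" * 5},
            # geneB is on '-': a '-' protospacer is coding there
            {"guide_id": "d", "spacer": "A" * 20, "pam_pos": 350, "strand": "-",
             "seed5": "A" * 5},
            # wholly between genes, no promoter
            {"guide_id": "e", "spacer": "A" * 20, "pam_pos": 260, "strand": "+",
             "seed5": "A" * 5},
        ])
        guides["multi_mapping"] = False
        guides["is_control"] = False
        out = annotate_guides(guides, anns).set_index("guide_id")
        assert out.loc["a", "orientation"] == "coding"
        assert out.loc["a", "target_gene"] == "geneA"
        assert out.loc["b", "orientation"] == "template"
        assert out.loc["c", "orientation"] == "promoter"
        assert out.loc["d", "orientation"] == "coding"
        assert out.loc["e", "orientation"] == "intergenic"
        # distances from the PAM-proximal base (pos 149 for guide a)
        assert out.loc["a", "dist_from_start"] == 149 - 100
        assert out.loc["a", "dist_from_end"] == 219 - 149
        # '-' gene: 5' end is the high coordinate; guide d proximal base 351
        assert out.loc["d", "dist_from_start"] == 419 - 351
        assert 0.0 <= out.loc["a", "rel_pos"] <= 1.0


class TestLoadGenome:
    def test_minimal_valid_input(self, tmp_path):
        (tmp_path / "g.fa").write_text(">g\nACGT\n")
        (tmp_path / "a.tsv").write_text(
            "gene\tstart\tend\tstrand\tessentiality\toperon\tpromoter\n"
            "g1\t0\t4\t+\tneutral\top1\t.\n")
        genome, anns = load_genome(tmp_path / "g.fa", tmp_path / "a.tsv")
        assert len(genome) == 4
        assert len(anns) == 1
        assert anns[0].essentiality == "neutral"

    def test_annotation_beyond_genome_rejected(self, tmp_path):
        (tmp_path / "g.fa").write_text(">g\nACGT\n")
        (tmp_path / "a.tsv").write_text(
            "gene\tstart\tend\tstrand\tessentiality\toperon\tpromoter\n"
            "g1\t0\t9\t+\tneutral\top1\t.\n")
        with pytest.raises(ValueError, match="exceeds genome length"):
            load_genome(tmp_path / "g.fa", tmp_path / "a.tsv")

    def test_non_acgt_rejected(self, tmp_path):
        (tmp_path / "g.fa").write_text(">g\nACGNT\n")
        (tmp_path / "a.tsv").write_text(
            "gene\tstart\tend\tstrand\tessentiality\toperon\tpromoter\n")
        with pytest.raises(ValueError, match="non-ACGT"):
            load_genome(tmp_path / "g.fa", tmp_path / "a.tsv")

    def test_unknown_essentiality_rejected(self):
        with pytest.raises(ValueError, match="essentiality"):
            GeneAnnotation("x", 0, 5, "+", "kind_of_important", "op")

    def test_gff3_missing_essentiality_names_gene(self, tmp_path):
        (tmp_path / "g.fa").write_text(">g\n" + "ACGT" * 10 + "\n")
        (tmp_path / "a.gff3").write_text(
            "##gff-version 3\n"
            "g\tsim\tgene\t1\t20\t.\t+\t.\tID=gene1;Name=mystery\n")
        with pytest.raises(ValueError, match="mystery"):
            load_genome(tmp_path / "g.fa", tmp_path / "a.gff3")

    def test_gff3_roundtrip(self, tmp_path):
        (tmp_path / "g.fa").write_text(">g\n" + "ACGT" * 20 + "\n")
        (tmp_path / "a.gff3").write_text(
            "##gff-version 3\n"
            "g\tsim\tgene\t11\t40\t.\t-\t.\t"
            "ID=gene1;Name=thrA;essentiality=essential;operon=op1;promoter=41-60\n")
        _, anns = load_genome(tmp_path / "g.fa", tmp_path / "a.gff3")
        a = anns[0]
        assert (a.start, a.end, a.strand) == (10, 40, "-")
        assert a.essentiality == "essential"
        assert a.promoter == (40, 60)
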