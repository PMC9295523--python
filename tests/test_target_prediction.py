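"""PPR-code readout, pattern compilation/rendering, and plastid target search."""

import numpy as np
import pytest

from pprscout.motif_detection import MotifArray, MotifHit
from pprscout.synthetic_data import SyntheticSpec, gen_plastid_genome
from pprscout.target_prediction import (
    DegeneratePattern,
    PlastidGene,
    build_pattern,
    TargetHit,
    classify_gene_function,
    extract_code_residues,
    flag_promiscuous,
    search_targets,
)


def _array(motifs_coords, seq_id="s1"):
    hits = tuple(
        MotifHit(seq_id=seq_id, motif_type=m, aa_start=a, aa_end=b, score=25.0)
        for m, a, b in motifs_coords
    )
    return MotifArray(seq_id=seq_id, hits=hits, sum_score=25.0 * len(hits))


class TestCodeResidues:
    def test_positional_readout(self):
        seq = "X" * 9 + "AbcdTefghijklmnopqrstuvwxyzabcdefgN".upper() + "X" * 5
        arr = _array([("P", 10, 44)])
        assert extract_code_residues(arr, {"s1": seq}) == [(0, "T", "N")]

    def test_short_motif_unknown(self):
        arr = _array([("P", 10, 13)])
        assert extract_code_residues(arr, {"s1": "A" * 30}) == [(0, None, None)]

    def test_non_code_bearing_motifs_skipped(self):
        seq = "A" * 100
        arr = _array([("L1", 1, 35), ("E1", 36, 70)])
        assert extract_code_residues(arr, {"s1": seq}) == []

    def test_out_of_bounds_raises_with_motif(self):
        arr = _array([("P", 10, 44)])
        with pytest.raises(ValueError, match="motif 0"):
            extract_code_residues(arr, {"s1": "A" * 20})


class TestCodeLookup:
    def test_known_pair(self, code_table):
        assert code_table.lookup(("T", "D")) == frozenset("G")
        assert code_table.lookup(("N", "N")) == frozenset("CU")

    def test_unknown_pair_full_set(self, code_table):
        assert code_table.lookup(("Q", "Q")) == frozenset("ACGU")
        assert code_table.lookup((None, "D")) == frozenset("ACGU")


class TestPattern:
    def test_build_renders_table_dialect(self):
        p = build_pattern([{"U"}, {"U"}, {"G"}, {"C", "U"}, {"C"}, {"G"}, {"C"}])
        assert p.render() == "UUG[CU]CGC"

    def test_full_sets_render_bracketed(self):
        p = build_pattern([frozenset("ACGU")] * 3)
        assert p.render() == "[ACGU][ACGU][ACGU]"

    def test_parse_round_trip_preserves_text(self):
        text = "UC[GC]UAU[AU][CU][ACGU]G"
        p = DegeneratePattern.parse(text)
        assert len(p) == 10
        assert p.render() == text

    def test_parse_render_parse_identity(self):
        for text in ("U[AU]UUU[AU]U[CAU][AC]U[AU]UU[ACGU][ACGU]", "UUG[CU]CGC"):
            p = DegeneratePattern.parse(text)
            assert DegeneratePattern.parse(p.render()).positions == p.positions

    def test_bad_pattern_rejected(self):
        with pytest.raises(ValueError):
            DegeneratePattern.parse("UUX")


def _gene(name, rna, features=None, ir=False):
    return PlastidGene(gene_name=name, rna_sequence=rna,
                       features=features or (("CDS", 1, len(rna)),),
                       ir_duplicate=ir)


class TestSearch:
    def test_published_example_matches(self):
        pattern = DegeneratePattern.parse("UUG[CU]CGC")
        gene = _gene("rbcL", "AAAAUUGCCGCAAAA")
        hits = search_targets(pattern, [gene])
        assert len(hits) == 1
        assert hits[0].matched_sequence == "UUGCCGC"
        assert hits[0].match_start == 5

    def test_published_intron_example(self):
        pattern = DegeneratePattern.parse("[UC][GC][GC]A[CU][CA]UAG[GU]")
        assert pattern.matches("UCGACAUAGU")

    def test_empty_gene_list(self):
        assert search_targets(DegeneratePattern.parse("UUU"), []) == []

    def test_overlapping_windows_reported(self):
        pattern = DegeneratePattern.parse("UU")
        hits = search_targets(pattern, [_gene("g", "UUUU")])
        assert [h.match_start for h in hits] == [1, 2, 3]

    def test_feature_context_at_midpoint(self):
        rna = "A" * 30 + "UUGCCGC" + "A" * 30
        gene = _gene("g", rna, features=(("CDS", 1, 30), ("intron", 31, 40),
                                         ("CDS", 41, len(rna))))
        hits = search_targets(DegeneratePattern.parse("UUG[CU]CGC"), [gene])
        assert hits[0].feature_context == "intron"

    def test_ir_duplicates_reported_once_and_flagged(self):
        rna = "AAAAUUGCCGCAAAA"
        genes = [_gene("ycf2", rna), _gene("ycf2", rna, ir=True)]
        hits = search_targets(DegeneratePattern.parse("UUG[CU]CGC"), genes)
        assert len(hits) == 1
        assert hits[0].ir_flagged

    def test_brute_force_completeness_small_genes(self):
        """Hit set equals brute-force window enumeration on genes <= 5 kb."""
        rng = np.random.default_rng(51)
        nts = np.array(list("ACGU"))
        genes = [
            _gene(f"g{i}", "".join(rng.choice(nts, size=int(rng.integers(200, 5000)))))
            for i in range(5)
        ]
        pattern = build_pattern(
            [frozenset(rng.choice(nts, size=int(rng.integers(1, 4)), replace=False))
             for _ in range(6)]
        )
        got = {(h.gene_name, h.match_start, h.matched_sequence)
               for h in search_targets(pattern, genes)}
        expected = set()
        for g in genes:
            rna = g.rna_sequence
            for i in range(len(rna) - len(pattern) + 1):
                window = rna[i: i + len(pattern)]
                if pattern.matches(window):
                    expected.add((g.gene_name, i + 1, window))
        assert got == expected

    def test_hits_revalidate_against_pattern(self):
        rng = np.random.default_rng(52)
        gene = _gene("g", "".join(rng.choice(list("ACGU"), size=2000)))
        pattern = DegeneratePattern.parse("[UC][GC]A[ACGU]U")
        for h in search_targets(pattern, [gene]):
            assert pattern.matches(h.matched_sequence)


class TestPromiscuity:
    def test_threshold_boundary(self):
        hits61 = [
            TargetHit(ppr_id="p", gene_name=f"g{i}", feature_context="CDS",
                      match_start=1, matched_sequence="UUU")
            for i in range(61)
        ]
        assert flag_promiscuous({"p": hits61}, threshold=60) == {"p"}
        assert flag_promiscuous({"p": hits61[:60]}, threshold=60) == set()
        assert flag_promiscuous({"p": []}, threshold=60) == set()

    def test_wildcard_pattern_flagged_with_count_oracle(self):
        """An all-wildcard 7-mer on the toy genome is promiscuous and its
        count equals the sliding-window total."""
        spec = SyntheticSpec(seed=13)
        genes, _ = gen_plastid_genome(spec)
        pattern = build_pattern([frozenset("ACGU")] * 7)
        hits = search_targets(pattern, genes, ppr_id="w")
        primary = {}
        for g in genes:
            primary.setdefault(g.gene_name, g)
        expected = sum(len(g.rna_sequence) - 6 for g in primary.values())
        assert len(hits) == expected
        assert flag_promiscuous({"w": hits}) == {"w"}


def test_gene_function_categories():
    assert classify_gene_function("psbD") == "photosynthesis"
    assert classify_gene_function("rbcL") == "photosynthesis"
    assert classify_gene_function("rps12") == "ribosomal_protein"
    assert classify_gene_function("trnK-UUU") == "tRNA"
    assert classify_gene_function("rrn23") == "rRNA"
    assert classify_gene_function("rpoC1") == "PEP_subunit"
    assert classify_gene_function("ycf1") == "unknown_function"
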