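import numpy as np
import pandas as pd
import pytest
from Bio.Align import substitution_matrices

import congevol as cv
from congevol.genetics import ProteinSequence
from congevol.orthology import make_aligner, score_all_pairs

BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN, GAP_EXT = 10.0, 0.5


def naive_global_score(a: str, b: str) -> float:
    """Independent affine-gap Needleman–Wunsch (Gotoh) in plain Python."""
    inf = float("inf")
    n, m = len(a), len(b)
    M = [[-inf] * (m + 1) for _ in range(n + 1)]
    X = [[-inf] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[-inf] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -GAP_OPEN - GAP_EXT * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = -GAP_OPEN - GAP_EXT * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - GAP_OPEN, X[i - 1][j] - GAP_EXT,
                          Y[i - 1][j] - GAP_OPEN)
            Y[i][j] = max(M[i][j - 1] - GAP_OPEN, Y[i][j - 1] - GAP_EXT,
                          X[i][j - 1] - GAP_OPEN)
    return max(M[n][m], X[n][m], Y[n][m])


def test_identical_sequence_scores_sum_of_diagonal():
    seq = "MKVLINGAGT"
    a = ProteinSequence("a", seq)
    row_a, row_b, score = cv.align_proteins_global(a, ProteinSequence("b", seq))
    assert row_a == row_b == seq
    assert score == sum(BLOSUM62[r, r] for r in seq)


def test_single_residue_gap_alignment():
    row_a, row_b, score = cv.align_proteins_global(
        ProteinSequence("a", "ACD"), ProteinSequence("b", "AD")
    )
    assert score == naive_global_score("ACD", "AD")
    assert row_a == "ACD"
    assert row_b in ("A-D", "AD-")  # C or D gapped, same score either way


def test_alignment_score_matches_naive_dp(rng):
    alphabet = "ARNDCQEGHILKMFPSTWYV"
    for _ in range(15):
        a = "".join(rng.choice(list(alphabet), size=8))
        b = "".join(rng.choice(list(alphabet), size=8))
        _, _, score = cv.align_proteins_global(
            ProteinSequence("a", a), ProteinSequence("b", b)
        )
        assert score == pytest.approx(naive_global_score(a, b))


def test_alignment_score_symmetric(rng):
    a = ProteinSequence("a", "MKVLING")
    b = ProteinSequence("b", "MKVING")
    _, _, s_ab = cv.align_proteins_global(a, b)
    _, _, s_ba = cv.align_proteins_global(b, a)
    assert s_ab == s_ba


def test_empty_sequence_rejected():
    with pytest.raises(ValueError, match="empty"):
        cv.align_proteins_global(
            ProteinSequence("a", ""), ProteinSequence("b", "MK")
        )


def _hits_from_matrix(scores, a_ids, b_ids):
    rows = []
    for i, a in enumerate(a_ids):
        for j, b in enumerate(b_ids):
            rows.append({"query": a, "subject": b,
                         "bitscore": scores[i][j], "pident": 0.0})
    return pd.DataFrame(rows)


def test_rbh_from_score_matrix():
    """Each gene pairs with its unique mutual best."""
    scores = [[9, 1, 1], [1, 8, 7], [1, 7, 8]]
    hits = _hits_from_matrix(scores, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
    pairs = cv.rbh_pairs(hits)
    assert {(p.a, p.b) for p in pairs} == {("a1", "b1"), ("a2", "b2"), ("a3", "b3")}


def test_rbh_tie_excludes_gene():
    scores = [[9, 9], [1, 2]]
    hits = _hits_from_matrix(scores, ["a1", "a2"], ["b1", "b2"])
    pairs = cv.rbh_pairs(hits)
    assert all(p.a != "a1" for p in pairs)


def test_rbh_symmetric():
    rng = np.random.default_rng(7)
    scores = rng.integers(1, 50, size=(4, 4)).tolist()
    a_ids, b_ids = [f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)]
    fwd = _hits_from_matrix(scores, a_ids, b_ids)
    rev = _hits_from_matrix(np.array(scores).T.tolist(), b_ids, a_ids)
    ab = {(p.a, p.b) for p in cv.rbh_pairs(fwd, rev)}
    ba = {(p.b, p.a) for p in cv.rbh_pairs(rev, fwd)}
    assert ab == ba


def test_identical_proteomes_pair_each_gene_with_twin():
    prots = [ProteinSequence(f"g{i}", s)
             for i, s in enumerate(["MKVLING", "MAACDEF", "MWYHQRK"])]
    prots_b = [ProteinSequence(p.id + "_b", p.residues) for p in prots]
    pairs = cv.rbh_pairs(score_all_pairs(prots, prots_b, make_aligner()))
    assert {(p.a, p.b) for p in pairs} == {
        (p.id, p.id + "_b") for p in prots
    }


def _pairs(mapping):
    return [cv.OrthologPair(a=a, b=b, score=1.0, pident=100.0)
            for a, b in mapping]


def test_single_copy_groups_are_rbh_triangles():
    """Groups form only when all three pairwise edges agree (brute force)."""
    ab = _pairs([("a1", "b1"), ("a2", "b2")])
    ac = _pairs([("a1", "c1"), ("a2", "c2")])
    bc = _pairs([("b1", "c1"), ("b2", "c9")])  # a2 triangle broken
    groups = cv.single_copy_groups(
        {("A", "B"): ab, ("A", "C"): ac, ("B", "C"): bc}, ["A", "B", "C"]
    )
    assert groups == [{"A": "a1", "B": "b1", "C": "c1"}]
    # brute-force check: every cross pair of the emitted group is an RBH edge
    edges = {("a1", "b1"), ("a1", "c1"), ("b1", "c1")}
    g = groups[0]
    assert {(g["A"], g["B"]), (g["A"], g["C"]), (g["B"], g["C"])} == edges


def test_missing_edge_blocks_group():
    ab = _pairs([("a1", "b1")])
    ac = _pairs([("a1", "c1")])
    groups = cv.single_copy_groups(
        {("A", "B"): ab, ("A", "C"): ac, ("B", "C"): []}, ["A", "B", "C"]
    )
    assert groups == []


def test_backtranslate_examples():
    cds = {
        "x": cv.CodingSequence("x", "ATGAAA"),
        "y": cv.CodingSequence("y", "ATGAAG"),
    }
    aln = cv.backtranslate_alignment({"x": "MK", "y": "MK"}, cds)
    assert aln.rows == ("ATGAAA", "ATGAAG")

    cds2 = {
        "x": cv.CodingSequence("x", "ATGAAA"),
        "y": cv.CodingSequence("y", "ATGGGGAAA"),
    }
    aln2 = cv.backtranslate_alignment({"x": "M-K", "y": "MGK"}, cds2)
    assert aln2.rows[0] == "ATG---AAA"


def test_backtranslate_mismatch_names_residue():
    cds = {
        "x": cv.CodingSequence("x", "ATGTGG"),  # MW
        "y": cv.CodingSequence("y", "ATGAAA"),  # MK
    }
    with pytest.raises(ValueError, match="residue 1"):
        cv.backtranslate_alignment({"x": "MK", "y": "MK"}, cds)


def test_backtranslate_then_ungap_recovers_cds(rng):
    code = cv.standard_code()
    sense = code.sense_codons
    seq_x = "".join(rng.choice(sense, size=20))
    seq_y = "".join(rng.choice(sense, size=18))
    cds = {
        "x": cv.CodingSequence("x", seq_x),
        "y": cv.CodingSequence("y", seq_y),
    }
    aln = cv.build_codon_alignment(cds["x"], cds["y"])
    assert aln.ungapped("x") == seq_x
    assert aln.ungapped("y") == seq_y


def test_simulated_families_recover_all_true_pairs():
    """RBH on simulated orthologs without paralogs recovers every pair."""
    tree = cv.parse_newick("(A:0.08,B:0.08);")
    config = cv.SimConfig(tree=tree, site_classes=[(1.0, 0.2)],
                          n_genes=12, codons_per_gene=60, seed=42)
    alignments, _ = cv.simulate_gene_set(config)
    prot_a, prot_b = [], []
    for gene, aln in alignments.items():
        cds_a = cv.CodingSequence(f"{gene}_A", aln.ungapped("A"))
        cds_b = cv.CodingSequence(f"{gene}_B", aln.ungapped("B"))
        prot_a.append(cv.translate(cds_a))
        prot_b.append(cv.translate(cds_b))
    pairs = cv.rbh_pairs(score_all_pairs(prot_a, prot_b))
    found = {(p.a, p.b) for p in pairs}
    expected = {(f"{g}_A", f"{g}_B") for g in alignments}
    assert len(found & expected) >= 0.99 * len(expected)
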