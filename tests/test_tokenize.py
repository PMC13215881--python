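"""Gene median dictionary, vocabulary, corpus filters and rank value encoding."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from rankcell import (
    GeneMedianDictionary,
    TokenVocabulary,
    balance_tissues,
    build_vocabulary,
    compute_nonzero_medians,
    deduplicate_studies,
    generate_corpus,
    qc_filter_cells,
    rank_value_encode,
    tokenize_corpus,
)
from rankcell.corpus import CorpusConfig, CountCorpus
from rankcell.tokenize import (
    MIN_PROTEIN_CODING_GENES,
    TokenizedDataset,
    apply_study_dedup,
    normalize_doi,
)


def make_corpus(counts, *, protein_coding=None, doi=None, tissue=None, malignant=None):
    """Assemble a CountCorpus around a dense (genes x cells) count matrix."""
    counts = np.asarray(counts)
    G, N = counts.shape
    gene_ids = [f"G{i:03d}" for i in range(G)]
    cell_ids = [f"c{j:03d}" for j in range(N)]
    gene_meta = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "token_id": -1,
            "protein_coding": protein_coding if protein_coding is not None else [True] * G,
            "class": "other",
            "regulator_of": "",
        }
    ).set_index("gene_id", drop=False)
    cell_meta = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "cell_type": "type_0",
            "tissue": tissue if tissue is not None else ["tissue_0"] * N,
            "study": [f"study_{j % 2}" for j in range(N)],
            "doi": doi if doi is not None else ["10.1/x"] * N,
            "batch": "batch_0",
            "platform": "cell",
            "preservation": "fresh",
            "malignant": malignant if malignant is not None else [False] * N,
            "disease": "healthy",
        }
    ).set_index("cell_id", drop=False)
    return CountCorpus(counts=sp.csr_matrix(counts), cell_meta=cell_meta, gene_meta=gene_meta)


class TestMedians:
    def test_single_nonzero_value_is_its_own_median(self):
        # all cells share the same total, so normalization to that total is a no-op
        counts = np.array([[0, 0, 3], [4, 4, 1]])
        d = compute_nonzero_medians(make_corpus(counts), target_sum=4.0)
        assert d.medians["G000"] == pytest.approx(3.0)

    def test_odd_count_median(self):
        counts = np.array([[1, 2, 4], [3, 2, 0]])
        d = compute_nonzero_medians(make_corpus(counts), target_sum=4.0)
        assert d.medians["G000"] == pytest.approx(2.0)

    def test_never_detected_gene_is_absent(self):
        counts = np.array([[0, 0], [1, 2]])
        d = compute_nonzero_medians(make_corpus(counts))
        assert "G000" not in d.medians

    def test_matches_brute_force_oracle_on_seeded_corpus(self):
        corpus = generate_corpus(CorpusConfig(n_genes=60, n_cells=50, seed=21))
        d = compute_nonzero_medians(corpus, exclude_malignant=True)
        counts = corpus.counts.toarray().astype(float)
        keep = ~corpus.cell_meta["malignant"].to_numpy(dtype=bool)
        counts = counts[:, keep]
        norm = counts / counts.sum(axis=0, keepdims=True) * d.target_sum
        for i, gid in enumerate(corpus.gene_meta["gene_id"]):
            vals = sorted(v for v in norm[i] if v > 0)
            if not vals:
                assert gid not in d.medians
                continue
            mid = len(vals) // 2
            expected = vals[mid] if len(vals) % 2 else 0.5 * (vals[mid - 1] + vals[mid])
            assert d.medians[gid] == pytest.approx(expected)

    def test_malignant_cells_change_the_dictionary_when_included(self):
        counts = np.array([[1, 9], [3, 1]])
        corpus = make_corpus(counts, malignant=[False, True])
        excl = compute_nonzero_medians(corpus, exclude_malignant=True, target_sum=4.0)
        incl = compute_nonzero_medians(corpus, exclude_malignant=False, target_sum=4.0)
        assert excl.medians != incl.medians

    def test_all_cells_malignant_raises(self):
        corpus = make_corpus(np.eye(2, dtype=int), malignant=[True, True])
        with pytest.raises(ValueError):
            compute_nonzero_medians(corpus, exclude_malignant=True)


class TestVocabulary:
    def test_total_size_is_gene_count_plus_four(self):
        genes = [f"ENSG{i:011d}" for i in range(20_271)]
        vocab = TokenVocabulary(gene_ids=genes)
        assert vocab.size == 20_275

    def test_single_gene_gives_size_five(self):
        d = GeneMedianDictionary(medians={"G1": 1.0})
        assert build_vocabulary(d).size == 5

    def test_roundtrip_preserves_id_mapping(self):
        d = GeneMedianDictionary(medians={"B": 1.0, "A": 2.0, "C": 0.5})
        vocab = build_vocabulary(d)
        back = TokenVocabulary.from_json(vocab.to_json())
        for g in d.medians:
            assert back.gene_token(g) == vocab.gene_token(g)
        assert back.content_hash() == vocab.content_hash()

    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            TokenVocabulary(gene_ids=["A", "A"])

    def test_specials_precede_genes_in_sorted_order(self):
        vocab = TokenVocabulary(gene_ids=["Z", "A"])
        assert vocab.gene_token("A") == 4
        assert vocab.gene_token("Z") == 5


class TestQCFilter:
    def test_cell_below_coding_threshold_removed_despite_noncoding(self):
        # cell 0: 6 coding + 9 noncoding detected -> removed; cell 1: 7 coding -> kept
        G = 16
        coding = [True] * 7 + [False] * 9
        counts = np.zeros((G, 2), dtype=int)
        counts[:6, 0] = 1
        counts[7:, 0] = 1
        counts[:7, 1] = 1
        corpus = make_corpus(counts, protein_coding=coding)
        filtered, log = qc_filter_cells(corpus)
        assert list(filtered.cell_meta["cell_id"]) == ["c001"]
        assert log["n_removed"] == 1

    def test_survivor_count_matches_direct_recount(self):
        corpus = generate_corpus(CorpusConfig(n_genes=40, n_cells=200,
                                              depth_lognormal_params=(3.0, 1.0), seed=9))
        filtered, log = qc_filter_cells(corpus)
        coding = corpus.gene_meta["protein_coding"].to_numpy()
        det = (corpus.counts.toarray()[coding] > 0).sum(axis=0)
        assert log["n_retained"] == int((det >= MIN_PROTEIN_CODING_GENES).sum())
        assert filtered.n_cells == log["n_retained"]


class TestDedup:
    def meta(self, pairs):
        return pd.DataFrame(
            {"cell_id": range(len(pairs)), "study": [p[0] for p in pairs], "doi": [p[1] for p in pairs]}
        )

    def test_shared_doi_keeps_smallest_accession(self):
        retained, log = deduplicate_studies(self.meta([("s2", "10.1/a"), ("s1", "10.1/a")]))
        assert retained == {"s1"}
        assert log["dropped"] == ["s2"]

    def test_distinct_dois_identity(self):
        retained, _ = deduplicate_studies(self.meta([("s1", "10.1/a"), ("s2", "10.1/b")]))
        assert retained == {"s1", "s2"}

    def test_three_duplicate_pairs_among_ten_studies_leaves_seven(self):
        pairs = [(f"s{i}", f"10.1/{i}") for i in range(7)]
        pairs += [("s7", "10.1/0"), ("s8", "10.1/1"), ("s9", "10.1/2")]
        retained, _ = deduplicate_studies(self.meta(pairs))
        assert len(retained) == 7

    def test_doi_normalization_rules(self):
        assert normalize_doi(" https://doi.org/10.1/ABC ") == "10.1/abc"
        retained, _ = deduplicate_studies(
            self.meta([("s1", "10.1/a"), ("s2", "HTTPS://DOI.ORG/10.1/A ")])
        )
        assert retained == {"s1"}

    def test_missing_doi_retained_but_flagged(self):
        retained, log = deduplicate_studies(self.meta([("s1", ""), ("s2", "10.1/b")]))
        assert retained == {"s1", "s2"}
        assert log["missing_doi"] == ["s1"]

    def test_idempotent(self, corpus_raw):
        once, log1 = apply_study_dedup(corpus_raw)
        twice, log2 = apply_study_dedup(once)
        assert sorted(once.cell_meta["cell_id"]) == sorted(twice.cell_meta["cell_id"])
        assert log2["dropped"] == []


class TestBalanceTissues:
    def test_already_balanced_is_identity(self):
        corpus = make_corpus(np.ones((3, 8), dtype=int), tissue=["t0"] * 4 + ["t1"] * 4)
        out = balance_tissues(corpus, cap=0.5, seed=0)
        assert out.n_cells == 8

    def test_cap_one_is_identity(self):
        corpus = make_corpus(np.ones((3, 6), dtype=int), tissue=["t0"] * 5 + ["t1"])
        assert balance_tissues(corpus, cap=1.0, seed=0).n_cells == 6

    def test_eighty_twenty_split_downsampled_to_cap(self):
        # cap must be feasible: with two tissues the floor is 1/2
        corpus = make_corpus(np.ones((3, 100), dtype=int), tissue=["t0"] * 80 + ["t1"] * 20)
        out = balance_tissues(corpus, cap=0.5, seed=1)
        shares = out.cell_meta["tissue"].value_counts(normalize=True)
        assert (shares <= 0.5 + 1e-9).all()
        # the minority tissue is never touched
        assert (out.cell_meta["tissue"] == "t1").sum() == 20

    def test_dominant_tissue_among_four_capped_at_quarter(self):
        tissue = ["t0"] * 70 + ["t1"] * 10 + ["t2"] * 10 + ["t3"] * 10
        corpus = make_corpus(np.ones((3, 100), dtype=int), tissue=tissue)
        out = balance_tissues(corpus, cap=0.25, seed=1)
        shares = out.cell_meta["tissue"].value_counts(normalize=True)
        assert (shares <= 0.25 + 1e-9).all()
        for t in ("t1", "t2", "t3"):
            assert (out.cell_meta["tissue"] == t).sum() == 10

    def test_infeasible_cap_rejected(self):
        corpus = make_corpus(np.ones((3, 9), dtype=int), tissue=["t0", "t1", "t2"] * 3)
        with pytest.raises(ValueError, match="infeasible"):
            balance_tissues(corpus, cap=0.2, seed=0)

    def test_deterministic_given_seed(self):
        corpus = make_corpus(np.ones((3, 100), dtype=int), tissue=["t0"] * 80 + ["t1"] * 20)
        a = balance_tissues(corpus, cap=0.5, seed=5)
        b = balance_tissues(corpus, cap=0.5, seed=5)
        assert list(a.cell_meta["cell_id"]) == list(b.cell_meta["cell_id"])


class TestRankValueEncode:
    vocab = TokenVocabulary(gene_ids=["A", "B", "C"])

    def test_median_scaling_reorders_equal_counts(self):
        d = GeneMedianDictionary(medians={"A": 2.0, "B": 0.5}, target_sum=4.0)
        enc = rank_value_encode([2, 2], ["A", "B"], d, self.vocab, capacity=10)
        # equal normalized values: score(B)=v/0.5 > score(A)=v/2 -> B first
        assert enc.tokens.tolist() == [
            self.vocab.CLS, self.vocab.gene_token("B"), self.vocab.gene_token("A"), self.vocab.EOS,
        ]

    def test_single_detected_gene(self):
        d = GeneMedianDictionary(medians={"A": 1.0})
        enc = rank_value_encode([5, 0], ["A", "B"], d, self.vocab, capacity=10)
        assert enc.tokens.tolist() == [self.vocab.CLS, self.vocab.gene_token("A"), self.vocab.EOS]

    def test_ties_broken_by_ascending_token_id(self):
        d = GeneMedianDictionary(medians={"A": 1.0, "B": 1.0, "C": 1.0}, target_sum=3.0)
        enc = rank_value_encode([1, 1, 1], ["C", "B", "A"], d, self.vocab, capacity=10)
        assert enc.gene_tokens.tolist() == [4, 5, 6]  # A, B, C

    def test_out_of_vocabulary_gene_dropped_and_counted(self):
        d = GeneMedianDictionary(medians={"A": 1.0})
        enc = rank_value_encode([1, 1], ["A", "X"], d, self.vocab, capacity=10)
        assert enc.n_dropped_out_of_vocab == 1
        assert enc.gene_tokens.tolist() == [self.vocab.gene_token("A")]

    def test_capacity_truncates_gene_list(self):
        d = GeneMedianDictionary(medians={"A": 1.0, "B": 1.0, "C": 1.0})
        enc = rank_value_encode([3, 2, 1], ["A", "B", "C"], d, self.vocab, capacity=3)
        assert len(enc.tokens) == 3
        assert enc.tokens[0] == self.vocab.CLS and enc.tokens[-1] == self.vocab.EOS

    def test_capacity_below_three_rejected(self):
        d = GeneMedianDictionary(medians={"A": 1.0})
        with pytest.raises(ValueError):
            rank_value_encode([1], ["A"], d, self.vocab, capacity=2)

    def test_rank_order_invariant_to_target_sum(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, size=12)
        genes = [f"G{i}" for i in range(12)]
        meds = {g: float(rng.uniform(0.5, 3.0)) for g in genes}
        vocab = TokenVocabulary(gene_ids=genes)
        orders = []
        for ts in (1.0, 10_000.0, 123.456):
            d = GeneMedianDictionary(medians=dict(meds), target_sum=ts)
            orders.append(rank_value_encode(counts, genes, d, vocab, capacity=20).tokens.tolist())
        assert orders[0] == orders[1] == orders[2]


class TestTokenizeCorpus:
    def test_record_count_lengths_and_determinism(self, pipeline):
        ds = pipeline["dataset"]
        corpus = pipeline["corpus"]
        assert len(ds) == corpus.n_cells
        # per-record length = min(detected in-vocab genes, capacity-2) + 2
        vocab, d = pipeline["vocab"], pipeline["dictionary"]
        counts = corpus.counts.toarray()
        gene_ids = corpus.gene_meta["gene_id"].tolist()
        in_vocab = np.array([vocab.gene_token(g) is not None for g in gene_ids])
        for j in range(0, corpus.n_cells, 97):
            detected = int(((counts[:, j] > 0) & in_vocab).sum())
            assert len(ds.tokens[j]) == min(detected, ds.capacity - 2) + 2
        ds2 = tokenize_corpus(corpus, d, vocab, capacity=ds.capacity)
        assert all(np.array_equal(a, b) for a, b in zip(ds.tokens, ds2.tokens))

    def test_encoding_is_a_permutation(self, pipeline):
        for t in pipeline["dataset"].tokens[:50]:
            genes = t[1:-1]
            assert len(set(genes.tolist())) == len(genes)
            assert t[0] == TokenVocabulary.CLS and t[-1] == TokenVocabulary.EOS

    def test_housekeeping_deprioritized_vs_absolute_ordering(self, pipeline):
        """Median-scaling pushes housekeeping genes to deeper ranks than raw expression."""
        corpus, vocab = pipeline["corpus"], pipeline["vocab"]
        ds = pipeline["dataset"]
        counts = corpus.counts.toarray()
        gene_ids = corpus.gene_meta["gene_id"].tolist()
        hk_tokens = {
            vocab.gene_token(g)
            for g, cl in zip(gene_ids, corpus.gene_meta["class"])
            if cl == "housekeeping" and vocab.gene_token(g) is not None
        }
        tok_of = {g: vocab.gene_token(g) for g in gene_ids}
        rve_pos, abs_pos = [], []
        for j in range(0, corpus.n_cells, 5):
            enc = ds.tokens[j][1:-1]
            for i, t in enumerate(enc):
                if int(t) in hk_tokens:
                    rve_pos.append(i)
            order = np.argsort(-counts[:, j], kind="stable")
            rank = 0
            for g in order:
                if counts[g, j] <= 0 or tok_of[gene_ids[g]] is None:
                    continue
                if rank >= len(enc):
                    break
                if tok_of[gene_ids[g]] in hk_tokens:
                    abs_pos.append(rank)
                rank += 1
        assert np.mean(rve_pos) > np.mean(abs_pos)

    def test_save_load_roundtrip(self, pipeline, tmp_path):
        ds = pipeline["heldout"]
        ds.save(tmp_path / "tok")
        back = TokenizedDataset.load(tmp_path / "tok")
        assert len(back) == len(ds)
        assert all(np.array_equal(a, b) for a, b in zip(back.tokens, ds.tokens))
        assert back.provenance_hash() == ds.provenance_hash()
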