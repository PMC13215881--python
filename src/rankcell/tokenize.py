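"""Rank value encoding: gene median dictionary, vocabulary, filters, tokenizer.

A cell's transcriptome is presented to the encoder as an ordered token
sequence: CLS, then the detected genes sorted by their *scaled* expression
(per-cell-normalized expression divided by the gene's corpus-wide non-zero
median), then EOS.  Scaling by the non-zero median deprioritizes
ubiquitously high housekeeping genes and promotes genes expressed near the
top of their own dynamic range, e.g. transcription factors.

Corpus-level preparation applies three filters before tokenization:

* QC: drop cells detecting fewer than 7 protein-coding genes,
* study deduplication by normalized DOI,
* tissue balancing so no tissue exceeds a share cap of the retained cells.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pyarrow as pa
import pyarrow.parquet as pq
import scipy.sparse as sp

from .corpus import CountCorpus

__all__ = [
    "TARGET_SUM",
    "MIN_PROTEIN_CODING_GENES",
    "GeneMedianDictionary",
    "TokenVocabulary",
    "RankValueEncoding",
    "TokenizedDataset",
    "compute_nonzero_medians",
    "build_vocabulary",
    "qc_filter_cells",
    "normalize_doi",
    "deduplicate_studies",
    "apply_study_dedup",
    "balance_tissues",
    "rank_value_encode",
    "tokenize_corpus",
]

#: Per-cell normalization target sum used both when computing the gene median
#: dictionary and when scoring genes at tokenization time.  Rank order is
#: invariant to this constant (scores scale uniformly within a cell).
TARGET_SUM = 10_000.0

#: QC threshold: minimum detected protein-coding genes per retained cell.
MIN_PROTEIN_CODING_GENES = 7


@dataclass
class GeneMedianDictionary:
    """gene id -> non-zero median of per-cell-normalized expression (s_g)."""

    medians: dict[str, float]
    target_sum: float = TARGET_SUM

    def __len__(self) -> int:
        return len(self.medians)

    def content_hash(self) -> str:
        payload = json.dumps(
            {"target_sum": self.target_sum, "medians": dict(sorted(self.medians.items()))},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_json(self) -> str:
        return json.dumps({"target_sum": self.target_sum, "medians": self.medians}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GeneMedianDictionary":
        d = json.loads(text)
        return cls(medians=d["medians"], target_sum=d["target_sum"])


@dataclass
class TokenVocabulary:
    """Gene tokens plus the four special tokens (pad, mask, CLS, EOS).

    Token ids are contiguous: specials occupy 0..3, genes follow in sorted
    gene-id order, so the total size is the gene count + 4.
    """

    gene_ids: list[str]

    PAD, MASK, CLS, EOS = 0, 1, 2, 3
    N_SPECIAL = 4
    SPECIAL_NAMES = ("<pad>", "<mask>", "<cls>", "<eos>")

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in vocabulary")
        self.gene_ids = sorted(self.gene_ids)
        self._gene_to_id = {g: i + self.N_SPECIAL for i, g in enumerate(self.gene_ids)}

    def __len__(self) -> int:
        return len(self.gene_ids) + self.N_SPECIAL

    @property
    def size(self) -> int:
        return len(self)

    def gene_token(self, gene_id: str) -> int | None:
        return self._gene_to_id.get(gene_id)

    def token_gene(self, token: int) -> str:
        if token < self.N_SPECIAL:
            return self.SPECIAL_NAMES[token]
        return self.gene_ids[token - self.N_SPECIAL]

    def is_gene_token(self, token: int) -> bool:
        return self.N_SPECIAL <= token < len(self)

    def content_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.gene_ids).encode()).hexdigest()[:16]

    def to_json(self) -> str:
        return json.dumps({"gene_ids": self.gene_ids}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TokenVocabulary":
        return cls(gene_ids=json.loads(text)["gene_ids"])


@dataclass
class RankValueEncoding:
    """One cell's token sequence: CLS, genes by descending scaled expression, EOS."""

    tokens: np.ndarray  # int32
    cell_id: str = ""
    n_dropped_out_of_vocab: int = 0

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def gene_tokens(self) -> np.ndarray:
        return self.tokens[1:-1]


@dataclass
class TokenizedDataset:
    """Per-cell token records with provenance for the dictionary/vocabulary."""

    tokens: list[np.ndarray]
    cell_meta: pd.DataFrame
    dictionary_hash: str
    vocabulary_hash: str
    capacity: int
    filter_log: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(t) for t in self.tokens], dtype=np.int64)

    def provenance_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.dictionary_hash.encode())
        h.update(self.vocabulary_hash.encode())
        for cid in self.cell_meta["cell_id"]:
            h.update(str(cid).encode())
        return h.hexdigest()[:16]

    def subset(self, idx: np.ndarray) -> "TokenizedDataset":
        idx = np.asarray(idx)
        return TokenizedDataset(
            tokens=[self.tokens[i] for i in idx],
            cell_meta=self.cell_meta.iloc[idx].copy(),
            dictionary_hash=self.dictionary_hash,
            vocabulary_hash=self.vocabulary_hash,
            capacity=self.capacity,
            filter_log=dict(self.filter_log),
        )

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table = pa.table(
            {
                "cell_id": pa.array(self.cell_meta["cell_id"].astype(str)),
                "tokens": pa.array([t.tolist() for t in self.tokens], type=pa.list_(pa.int32())),
                "length": pa.array([len(t) for t in self.tokens], type=pa.int32()),
            }
        )
        pq.write_table(table, outdir / "records.parquet")
        self.cell_meta.to_csv(outdir / "cell_meta.tsv", sep="\t", index=False)
        manifest = {
            "dictionary_hash": self.dictionary_hash,
            "vocabulary_hash": self.vocabulary_hash,
            "capacity": self.capacity,
            "n_records": len(self),
            "filter_log": self.filter_log,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, indir: str | Path) -> "TokenizedDataset":
        indir = Path(indir)
        manifest = json.loads((indir / "manifest.json").read_text())
        table = pq.read_table(indir / "records.parquet")
        tokens = [np.asarray(t, dtype=np.int32) for t in table["tokens"].to_pylist()]
        cell_meta = pd.read_csv(indir / "cell_meta.tsv", sep="\t").set_index(
            "cell_id", drop=False
        )
        return cls(
            tokens=tokens,
            cell_meta=cell_meta,
            dictionary_hash=manifest["dictionary_hash"],
            vocabulary_hash=manifest["vocabulary_hash"],
            capacity=manifest["capacity"],
            filter_log=manifest.get("filter_log", {}),
        )


# --------------------------------------------------------------------------
# Dictionary & vocabulary


def _normalized_csc(counts: sp.spmatrix, target_sum: float) -> sp.csc_matrix:
    """Scale each cell (column) to the target sum; cells with zero total kept as zero."""
    csc = sp.csc_matrix(counts, dtype=np.float64)
    totals = np.asarray(csc.sum(axis=0)).ravel()
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals), where=totals > 0)
    return csc @ sp.diags(scale)


def compute_nonzero_medians(
    corpus: CountCorpus, exclude_malignant: bool = True, target_sum: float = TARGET_SUM
) -> GeneMedianDictionary:
    """Non-zero median of normalized expression per detected gene.

    Cells flagged malignant (high mutational burden) are excluded when
    ``exclude_malignant`` is set.  Genes never detected in the qualifying
    cells are absent from the result.
    """
    keep = np.ones(corpus.n_cells, dtype=bool)
    if exclude_malignant and "malignant" in corpus.cell_meta:
        keep &= ~corpus.cell_meta["malignant"].to_numpy(dtype=bool)
    if not keep.any():
        raise ValueError("no cells remain after malignant-cell exclusion")
    norm = _normalized_csc(corpus.counts[:, keep], target_sum).tocsr()
    medians: dict[str, float] = {}
    gene_ids = corpus.gene_meta["gene_id"].tolist()
    for g in range(norm.shape[0]):
        row = norm.data[norm.indptr[g] : norm.indptr[g + 1]]
        row = row[row > 0]
        if row.size:
            medians[gene_ids[g]] = float(np.median(row))
    return GeneMedianDictionary(medians=medians, target_sum=target_sum)


def build_vocabulary(dictionary: GeneMedianDictionary) -> TokenVocabulary:
    if not dictionary.medians:
        raise ValueError("empty gene median dictionary")
    return TokenVocabulary(gene_ids=list(dictionary.medians))


# --------------------------------------------------------------------------
# Corpus-level filters


def qc_filter_cells(corpus: CountCorpus) -> tuple[CountCorpus, dict]:
    """Drop cells detecting fewer than 7 protein-coding genes."""
    coding = corpus.gene_meta["protein_coding"].to_numpy(dtype=bool)
    detected = np.asarray((corpus.counts[coding] > 0).sum(axis=0)).ravel()
    keep = detected >= MIN_PROTEIN_CODING_GENES
    log = {
        "rule": f"min {MIN_PROTEIN_CODING_GENES} detected protein-coding genes",
        "n_input": int(corpus.n_cells),
        "n_removed": int((~keep).sum()),
        "n_retained": int(keep.sum()),
    }
    return corpus.subset_cells(keep), log


def normalize_doi(doi: str) -> str:
    d = str(doi).strip().lower()
    for prefix in ("https://doi.org/", "http://doi.org/", "doi:"):
        if d.startswith(prefix):
            d = d[len(prefix) :]
    return d.strip()


def deduplicate_studies(cell_meta: pd.DataFrame) -> tuple[set[str], dict]:
    """One study per distinct normalized DOI (smallest accession wins)."""
    pairs = cell_meta[["study", "doi"]].drop_duplicates()
    retained: set[str] = set()
    dropped: list[str] = []
    missing: list[str] = []
    by_doi: dict[str, list[str]] = {}
    for study, doi in pairs.itertuples(index=False):
        nd = normalize_doi(doi) if pd.notna(doi) else ""
        if not nd:
            retained.add(study)
            missing.append(study)
            continue
        by_doi.setdefault(nd, []).append(study)
    for nd, studies in by_doi.items():
        studies = sorted(studies)
        retained.add(studies[0])
        dropped.extend(studies[1:])
    log = {
        "n_studies": int(pairs["study"].nunique()),
        "retained": sorted(retained),
        "dropped": sorted(dropped),
        "missing_doi": sorted(missing),
    }
    return retained, log


def apply_study_dedup(corpus: CountCorpus) -> tuple[CountCorpus, dict]:
    retained, log = deduplicate_studies(corpus.cell_meta)
    keep = corpus.cell_meta["study"].isin(retained).to_numpy()
    return corpus.subset_cells(keep), log


def balance_tissues(corpus: CountCorpus, cap: float = 0.25, seed: int = 0) -> CountCorpus:
    """Downsample over-represented tissues until each holds <= ``cap`` of cells.

    Iterative: the most over-cap tissue is downsampled (uniformly, without
    replacement) to exactly the cap share of the current retained total, which
    can push other tissues over the cap; repeats until stable.
    """
    tissues = corpus.cell_meta["tissue"].to_numpy()
    n_tissues = len(np.unique(tissues))
    if not (1.0 / n_tissues <= cap <= 1.0):
        raise ValueError(f"cap {cap} infeasible for {n_tissues} tissues (need >= {1/n_tissues:.3f})")
    rng = np.random.default_rng(seed)
    keep = np.ones(len(tissues), dtype=bool)
    while True:
        labels, counts = np.unique(tissues[keep], return_counts=True)
        total = keep.sum()
        shares = counts / total
        over = shares > cap + 1e-12
        if not over.any():
            break
        worst = labels[np.argmax(shares)]
        idx = np.flatnonzero(keep & (tissues == worst))
        # target size solving n_t / (total - removed) = cap
        target = int(np.floor(cap * (total - len(idx)) / (1.0 - cap)))
        target = max(target, 1)
        drop = rng.choice(idx, size=len(idx) - target, replace=False)
        keep[drop] = False
    return corpus.subset_cells(keep)


# --------------------------------------------------------------------------
# Encoding


def rank_value_encode(
    cell_counts: np.ndarray,
    gene_ids: list[str] | np.ndarray,
    dictionary: GeneMedianDictionary,
    vocab: TokenVocabulary,
    capacity: int = 2048,
    cell_id: str = "",
) -> RankValueEncoding:
    """Encode one cell: CLS, genes by descending median-scaled expression, EOS.

    ``capacity`` counts the full sequence including CLS and EOS, so at most
    ``capacity - 2`` gene tokens are kept.  Ties in the score are broken by
    ascending token id.  Detected genes missing from the dictionary are
    dropped silently but counted.
    """
    if capacity < 3:
        raise ValueError("capacity must be >= 3 (CLS + 1 gene + EOS)")
    counts = np.asarray(cell_counts, dtype=np.float64).ravel()
    total = counts.sum()
    norm = counts * (dictionary.target_sum / total) if total > 0 else counts

    toks: list[int] = []
    scores: list[float] = []
    dropped = 0
    for g in np.flatnonzero(counts > 0):
        gid = str(gene_ids[g])
        s_g = dictionary.medians.get(gid)
        tok = vocab.gene_token(gid)
        if s_g is None or tok is None:
            dropped += 1
            continue
        toks.append(tok)
        scores.append(norm[g] / s_g)
    order = sorted(range(len(toks)), key=lambda i: (-scores[i], toks[i]))
    ranked = [toks[i] for i in order][: capacity - 2]
    seq = np.array([vocab.CLS] + ranked + [vocab.EOS], dtype=np.int32)
    return RankValueEncoding(tokens=seq, cell_id=cell_id, n_dropped_out_of_vocab=dropped)


def tokenize_corpus(
    corpus: CountCorpus,
    dictionary: GeneMedianDictionary,
    vocab: TokenVocabulary,
    capacity: int = 2048,
    filter_log: dict | None = None,
) -> TokenizedDataset:
    """Rank-value-encode every cell of a (filtered) corpus."""
    csc = sp.csc_matrix(corpus.counts)
    gene_ids = corpus.gene_meta["gene_id"].tolist()
    tokens = []
    dropped_total = 0
    cell_ids = corpus.cell_meta["cell_id"].tolist()
    for j in range(corpus.n_cells):
        col = np.zeros(corpus.n_genes)
        sl = slice(csc.indptr[j], csc.indptr[j + 1])
        col[csc.indices[sl]] = csc.data[sl]
        enc = rank_value_encode(col, gene_ids, dictionary, vocab, capacity, cell_ids[j])
        tokens.append(enc.tokens)
        dropped_total += enc.n_dropped_out_of_vocab
    log = dict(filter_log or {})
    log["n_out_of_vocab_dropped"] = int(dropped_total)
    return TokenizedDataset(
        tokens=tokens,
        cell_meta=corpus.cell_meta.copy(),
        dictionary_hash=dictionary.content_hash(),
        vocabulary_hash=vocab.content_hash(),
        capacity=capacity,
        filter_log=log,
    )
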