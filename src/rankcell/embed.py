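"""Contextual gene/cell embeddings, robustness suites, probes and fine-tuning.

A forward pass embeds every token of a cell's rank value encoding; the
hidden state at a gene's position is that gene's *contextual* embedding in
that cell, and the hidden state at the CLS position is the cell embedding.
Zero-shot analyses use the second-to-last layer (the last layer is more
tied to the masked-LM objective); fine-tuned analyses may use the last.

Batch-robustness is quantified by comparing cosine-similarity distributions
between sampled pairs: different genes from the same cell (expected low),
the same gene across cells of one cell type within a batch (expected high),
and the same gene across batches (high iff embeddings are robust to the
batch artifact).  Arms are compared by two-sided rank-sum tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score

from . import _nn
from ._nn import IGNORE_LABEL, AdamW, cosine_warmup_lr
from .encoder import EncoderModel, iterate_batches, pad_batch
from .tokenize import TokenVocabulary, TokenizedDataset

__all__ = [
    "EmbeddingMatrix",
    "ProbeResult",
    "FinetuneConfig",
    "extract_gene_embeddings",
    "extract_cell_embeddings",
    "cosine_similarity",
    "cosine_similarity_suite",
    "separability_index",
    "linear_probe",
    "finetune_classifier",
]


@dataclass
class EmbeddingMatrix:
    """Rows of embedding vectors plus an entity index.

    For gene-level matrices the index has columns (cell_id, gene_token,
    position); for cell-level matrices just cell_id.
    """

    vectors: np.ndarray  # (n, d)
    index: pd.DataFrame
    layer_tag: str
    model_hash: str = ""

    def __len__(self) -> int:
        return len(self.vectors)


def _forward_batches(model: EncoderModel, dataset: TokenizedDataset, batch_size: int):
    for chunk, (ids, lengths) in iterate_batches(dataset, batch_size):
        hs = model.forward_hidden(ids, lengths, train=False)
        yield chunk, ids, lengths, hs


def extract_gene_embeddings(
    model: EncoderModel,
    dataset: TokenizedDataset,
    layer_tag: str = "second_to_last",
    batch_size: int = 16,
) -> EmbeddingMatrix:
    """One vector per (gene token, cell) at the gene's position in the encoding."""
    rows, cells, genes, positions = [], [], [], []
    cell_ids = dataset.cell_meta["cell_id"].tolist()
    for chunk, ids, lengths, hs in _forward_batches(model, dataset, batch_size):
        h = model.hidden_at(hs, layer_tag)
        for b, i in enumerate(chunk):
            L = int(lengths[b])
            for pos in range(1, L - 1):  # skip CLS (0) and EOS (L-1)
                rows.append(h[b, pos])
                cells.append(cell_ids[i])
                genes.append(int(ids[b, pos]))
                positions.append(pos)
    index = pd.DataFrame({"cell_id": cells, "gene_token": genes, "position": positions})
    return EmbeddingMatrix(
        vectors=np.asarray(rows), index=index, layer_tag=layer_tag, model_hash=model.weight_hash()
    )


def extract_cell_embeddings(
    model: EncoderModel,
    dataset: TokenizedDataset,
    layer_tag: str = "second_to_last",
    batch_size: int = 16,
) -> EmbeddingMatrix:
    """One vector per cell: the CLS-position hidden state at the tagged layer."""
    for t in dataset.tokens:
        if len(t) == 0 or t[0] != TokenVocabulary.CLS:
            raise ValueError("encodings must begin with CLS")
    rows, cells = [], []
    cell_ids = dataset.cell_meta["cell_id"].tolist()
    for chunk, ids, lengths, hs in _forward_batches(model, dataset, batch_size):
        h = model.hidden_at(hs, layer_tag)
        for b, i in enumerate(chunk):
            rows.append(h[b, 0])
            cells.append(cell_ids[i])
    index = pd.DataFrame({"cell_id": cells})
    return EmbeddingMatrix(
        vectors=np.asarray(rows), index=index, layer_tag=layer_tag, model_hash=model.weight_hash()
    )


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for a zero-norm vector")
    return float(np.dot(u, v) / (nu * nv))


def _sample_pairs(rng, candidates, n_pairs):
    out = []
    for _ in range(n_pairs):
        group = candidates[rng.integers(len(candidates))]
        i, j = rng.choice(len(group), size=2, replace=False)
        out.append((group[i], group[j]))
    return out


def cosine_similarity_suite(
    emb: EmbeddingMatrix,
    cell_meta: pd.DataFrame,
    n_pairs: int = 100,
    seed: int = 0,
) -> dict:
    """Gene-embedding robustness arms and pairwise rank-sum tests.

    Arms: ``different_gene_same_cell``, ``same_gene_same_batch`` (same cell
    type), ``same_gene_cross_batch`` (same cell type).  Zero-norm vectors are
    excluded and counted in the log.
    """
    rng = np.random.default_rng(seed)
    idx = emb.index.copy().reset_index(drop=True)
    norms = np.linalg.norm(emb.vectors, axis=1)
    ok = norms > 0
    excluded = int((~ok).sum())
    idx = idx[ok].reset_index(drop=True)
    vec = emb.vectors[ok]
    meta = cell_meta.set_index("cell_id") if "cell_id" in cell_meta.columns else cell_meta
    idx = idx.join(meta[["cell_type", "batch"]], on="cell_id")

    def sims(pairs):
        return np.array([cosine_similarity(vec[i], vec[j]) for i, j in pairs])

    arms: dict[str, np.ndarray] = {}
    # arm 1: two different genes within one cell
    by_cell = [g.index.to_numpy() for _, g in idx.groupby("cell_id") if len(g) >= 2]
    if by_cell:
        arms["different_gene_same_cell"] = sims(_sample_pairs(rng, by_cell, n_pairs))
    # arms 2/3: same gene, same cell type, across cells within/between batches
    same_batch, cross_batch = [], []
    for (_, _), g in idx.groupby(["gene_token", "cell_type"]):
        if len(g) < 2:
            continue
        batches = g["batch"].to_numpy()
        rows = g.index.to_numpy()
        same = [rows[batches == b] for b in np.unique(batches)]
        same = [r for r in same if len(r) >= 2]
        same_batch.extend(same)
        if len(np.unique(batches)) >= 2:
            cross_batch.append(rows)
    if same_batch:
        arms["same_gene_same_batch"] = sims(_sample_pairs(rng, same_batch, n_pairs))
    if cross_batch:
        pairs = []
        tries = 0
        while len(pairs) < n_pairs and tries < 50 * n_pairs:
            tries += 1
            rows = cross_batch[rng.integers(len(cross_batch))]
            i, j = rng.choice(len(rows), size=2, replace=False)
            if idx.loc[rows[i], "batch"] != idx.loc[rows[j], "batch"]:
                pairs.append((rows[i], rows[j]))
        if pairs:
            arms["same_gene_cross_batch"] = sims(pairs)

    tests = {}
    names = list(arms)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            method = "exact" if (len(arms[a]) <= 25 and len(arms[b]) <= 25) else "auto"
            res = scipy.stats.mannwhitneyu(arms[a], arms[b], alternative="two-sided", method=method)
            tests[f"{a}_vs_{b}"] = {"statistic": float(res.statistic), "p": float(res.pvalue)}
    return {"arms": arms, "tests": tests, "log": {"n_zero_norm_excluded": excluded}}


def separability_index(
    vectors: np.ndarray,
    gene_labels: np.ndarray,
    min_detections: int = 2,
) -> tuple[float, dict]:
    """Fraction of embeddings whose cosine nearest neighbor shares the gene.

    Genes with fewer than ``min_detections`` embeddings are excluded (a
    nearest same-gene neighbor must exist in principle).  Ties are broken by
    the smallest row index.
    """
    gene_labels = np.asarray(gene_labels)
    labels, counts = np.unique(gene_labels, return_counts=True)
    keep_genes = set(labels[counts >= max(2, min_detections)])
    mask = np.array([g in keep_genes for g in gene_labels])
    log = {"n_excluded_single": int((~mask).sum()), "n_used": int(mask.sum())}
    v = np.asarray(vectors, dtype=float)[mask]
    lab = gene_labels[mask]
    if len(v) == 0:
        raise ValueError("no genes with enough replicate embeddings")
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    u = v / norms
    sim = u @ u.T
    np.fill_diagonal(sim, -np.inf)
    nn = sim.argmax(axis=1)  # argmax takes the first (smallest index) tie
    frac = float(np.mean(lab[nn] == lab))
    return frac, log


@dataclass
class ProbeResult:
    task: str
    mode: str  # zero_shot | few_shot | fine_tune
    scores: dict = field(default_factory=dict)  # seed -> macro F1 (gene) or dict (cell)
    split: dict = field(default_factory=dict)

    @property
    def mean_score(self) -> float:
        vals = [
            v if np.isscalar(v) else float(np.mean(list(v.values())))
            for v in self.scores.values()
        ]
        return float(np.mean(vals))


def linear_probe(
    vectors: np.ndarray,
    labels: np.ndarray,
    groups: np.ndarray | None = None,
    seeds=(0, 1, 2),
    test_fraction: float = 0.2,
    task: str = "probe",
) -> ProbeResult:
    """Multinomial linear classifier on frozen embeddings.

    ``groups`` (e.g. the gene identity of each row) makes the split
    group-wise: train on 80% of the groups, score macro F1 on the held-out
    20%.  Without groups, rows are split directly (cell-level tasks) and
    per-class F1 is reported alongside the macro.
    """
    labels = np.asarray(labels)
    vectors = np.asarray(vectors, dtype=float)
    result = ProbeResult(task=task, mode="zero_shot")
    for seed in seeds:
        # salt the stream so the split never replays another seeded
        # permutation of the same length (e.g. the corpus generator's)
        rng = np.random.default_rng([int(seed), 0x5EED])
        if groups is not None:
            ug = np.unique(np.asarray(groups))
            rng.shuffle(ug)
            n_test = max(1, int(round(test_fraction * len(ug))))
            test_groups = set(ug[:n_test].tolist())
            test_mask = np.array([g in test_groups for g in groups])
        else:
            order = rng.permutation(len(labels))
            n_test = max(1, int(round(test_fraction * len(labels))))
            test_mask = np.zeros(len(labels), dtype=bool)
            test_mask[order[:n_test]] = True
        train_mask = ~test_mask
        train_classes = set(np.unique(labels[train_mask]).tolist())
        missing = set(np.unique(labels).tolist()) - train_classes
        if len(train_classes) < 2:
            raise ValueError("fewer than 2 classes present in the training split")
        if missing:
            raise ValueError(f"classes absent from training split: {sorted(missing)}")
        clf = LogisticRegression(max_iter=2000, C=10.0)
        clf.fit(vectors[train_mask], labels[train_mask])
        pred = clf.predict(vectors[test_mask])
        macro = float(f1_score(labels[test_mask], pred, average="macro"))
        result.scores[int(seed)] = macro
        result.split[int(seed)] = {
            "n_train": int(train_mask.sum()),
            "n_test": int(test_mask.sum()),
        }
    return result


@dataclass(frozen=True)
class FinetuneConfig:
    """Fine-tuning defaults: 1 epoch, 1% warm-up, cosine decay.

    Example budgets follow the published protocol (100 cells few-shot,
    10,000 cells full) scaled to the desk profile (20 / 400).
    """

    max_lr: float = 5e-4
    warmup_ratio: float = 0.01
    weight_decay: float = 0.0
    batch_size: int = 8
    epochs: float = 1.0
    few_shot_cells: int = 20
    full_cells: int = 400
    seed: int = 0


def _head_forward(h, Wc, bc):
    return h @ Wc + bc


def finetune_classifier(
    model: EncoderModel,
    train_ds: TokenizedDataset,
    train_labels,
    eval_ds: TokenizedDataset,
    eval_labels,
    head: str = "cell",
    mode: str = "few_shot",
    layer_tag: str = "last",
    config: FinetuneConfig | None = None,
    task: str = "finetune",
) -> tuple[ProbeResult, EncoderModel]:
    """Fine-tune with a classification head at the CLS or gene-token positions.

    ``head="cell"``: ``*_labels`` are integer class arrays, one per cell.
    ``head="gene"``: ``*_labels`` are dicts mapping gene token -> class;
    every occurrence of a labeled gene is a training/evaluation position.
    When the model carries LoRA adapters (``model.frozen_base``), only the
    adapters and the head are updated; otherwise all layers are unfrozen.
    """
    cfg = config or FinetuneConfig()
    if head not in ("cell", "gene"):
        raise ValueError("head must be 'cell' or 'gene'")
    if mode not in ("few_shot", "full"):
        raise ValueError("mode must be 'few_shot' or 'full'")
    model = model.copy()
    rng = np.random.default_rng(cfg.seed)

    budget = cfg.few_shot_cells if mode == "few_shot" else cfg.full_cells
    if budget < len(train_ds):
        pick = rng.choice(len(train_ds), size=budget, replace=False)
        train_ds = train_ds.subset(pick)
        if head == "cell":
            train_labels = np.asarray(train_labels)[pick]

    if head == "cell":
        classes = sorted(set(np.asarray(train_labels).tolist()) | set(np.asarray(eval_labels).tolist()))
    else:
        classes = sorted(set(train_labels.values()) | set(eval_labels.values()))
    cls_index = {c: i for i, c in enumerate(classes)}
    n_classes = len(classes)
    d = model.spec.hidden_size
    Wc = rng.normal(0.0, model.spec.init_std, size=(d, n_classes))
    bc = np.zeros(n_classes)
    head_params = {"head.Wc": Wc, "head.bc": bc}

    if model.frozen_base:
        trainable = dict(head_params)
        for name, ad in model.adapters.items():
            trainable[f"lora.{name}.A"] = ad["A"]
            trainable[f"lora.{name}.B"] = ad["B"]
    else:
        trainable = {**model.params, **head_params}

    layer_index = model.spec.layers if layer_tag == "last" else model.spec.layers - 1
    steps_per_epoch = int(np.ceil(len(train_ds) / cfg.batch_size))
    total_steps = max(1, int(round(cfg.epochs * steps_per_epoch))) if cfg.epochs > 0 else 0
    opt = AdamW(trainable, lr=cfg.max_lr, weight_decay=cfg.weight_decay)
    drop_rng = np.random.default_rng(cfg.seed + 1)

    def batch_positions(ids, lengths, chunk, labels):
        """(rows, cols, class indices) of supervised positions in this batch."""
        if head == "cell":
            rows = np.arange(len(chunk))
            cols = np.zeros(len(chunk), dtype=int)
            y = np.array([cls_index[np.asarray(labels)[i]] for i in chunk])
            return rows, cols, y
        rows, cols, y = [], [], []
        for b in range(ids.shape[0]):
            for pos in range(1, int(lengths[b]) - 1):
                lab = labels.get(int(ids[b, pos]))
                if lab is not None:
                    rows.append(b)
                    cols.append(pos)
                    y.append(cls_index[lab])
        return np.array(rows, int), np.array(cols, int), np.array(y, int)

    step = 0
    train_label_arr = train_labels
    while step < total_steps:
        for chunk, (ids, lengths) in iterate_batches(train_ds, cfg.batch_size, rng, shuffle=True):
            if step >= total_steps:
                break
            rows, cols, y = batch_positions(ids, lengths, chunk, train_label_arr)
            if len(y) == 0:
                continue
            hs, cache = _nn.forward(
                model.params, model.spec, ids, lengths, train=True, rng=drop_rng,
                adapters=model.adapters or None, qweights=model.qweights or None,
            )
            h = hs[layer_index]
            z = _head_forward(h[rows, cols], Wc, bc)
            z = z - z.max(axis=1, keepdims=True)
            logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
            loss = -logp[np.arange(len(y)), y].mean()
            dz = np.exp(logp)
            dz[np.arange(len(y)), y] -= 1.0
            dz /= len(y)
            x = h[rows, cols]
            gWc = x.T @ dz
            gbc = dz.sum(axis=0)
            d_h = np.zeros_like(h)
            np.add.at(d_h, (rows, cols), dz @ Wc.T)
            grads, lora_grads = {}, {}
            _nn.backward_hidden(
                model.params, model.spec, cache, d_h, from_layer=layer_index,
                grads=grads, lora_grads=lora_grads,
                adapters=model.adapters or None, qweights=model.qweights or None,
            )
            gall = {"head.Wc": gWc, "head.bc": gbc}
            if model.frozen_base:
                for (name, mat), g in lora_grads.items():
                    gall[f"lora.{name}.{mat}"] = g
            else:
                gall.update(grads)
            lr = cosine_warmup_lr(step, total_steps, cfg.max_lr, cfg.warmup_ratio)
            opt.step(trainable, gall, lr=lr)
            step += 1

    # evaluation
    preds, truth = [], []
    for chunk, (ids, lengths) in iterate_batches(eval_ds, cfg.batch_size):
        rows, cols, y = batch_positions(ids, lengths, chunk, eval_labels)
        if len(y) == 0:
            continue
        hs = model.forward_hidden(ids, lengths, train=False)
        h = model.hidden_at(hs, layer_tag) if layer_tag in ("last", "second_to_last") else hs[layer_index]
        z = _head_forward(h[rows, cols], Wc, bc)
        preds.extend(z.argmax(axis=1).tolist())
        truth.extend(y.tolist())
    result = ProbeResult(task=task, mode=mode)
    if head == "gene":
        result.scores[cfg.seed] = float(f1_score(truth, preds, average="macro"))
    else:
        per_class = f1_score(truth, preds, average=None, labels=list(range(n_classes)))
        result.scores[cfg.seed] = {str(classes[i]): float(per_class[i]) for i in range(n_classes)}
    result.split[cfg.seed] = {"n_train_cells": len(train_ds), "n_eval_cells": len(eval_ds)}
    model.head = head_params  # type: ignore[attr-defined]
    return result, model
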