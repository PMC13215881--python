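"""Shared fixtures: one synthetic study corpus and one pretrained tiny encoder.

The session pipeline mirrors the intended workflow — generate a corpus with
planted structure, layer mild batch artifacts on top, apply QC / DOI
deduplication / tissue balancing, build the gene median dictionary and
vocabulary, tokenize at capacity 64, and pretrain a 2-layer family member —
so every analysis-level test runs against the same trained model.
"""

import numpy as np
import pytest

from rankcell import (
    BatchEffectConfig,
    CorpusConfig,
    MaskingConfig,
    TrainConfig,
    balance_tissues,
    build_spec,
    build_vocabulary,
    compute_nonzero_medians,
    generate_corpus,
    inject_batch_effects,
    pretrain,
    qc_filter_cells,
    quantize_model,
    tokenize_corpus,
)
from rankcell.tokenize import apply_study_dedup

CAPACITY = 64


@pytest.fixture(scope="session")
def corpus_raw():
    return generate_corpus(CorpusConfig())


@pytest.fixture(scope="session")
def corpus_fx(corpus_raw):
    return inject_batch_effects(
        corpus_raw, BatchEffectConfig(nucleus_dropout=0.1, frozen_depth_scale=1.3, seed=1)
    )


@pytest.fixture(scope="session")
def pipeline(corpus_fx):
    c, qc_log = qc_filter_cells(corpus_fx)
    c, dedup_log = apply_study_dedup(c)
    c = balance_tissues(c, cap=0.25, seed=0)
    dictionary = compute_nonzero_medians(c, exclude_malignant=True)
    vocab = build_vocabulary(dictionary)
    ds = tokenize_corpus(c, dictionary, vocab, capacity=CAPACITY,
                         filter_log={"qc": qc_log, "dedup": dedup_log})
    rng = np.random.default_rng(0)
    order = rng.permutation(len(ds))
    n_train = int(0.8 * len(ds))
    return {
        "corpus": c,
        "dictionary": dictionary,
        "vocab": vocab,
        "dataset": ds,
        "train": ds.subset(order[:n_train]),
        "heldout": ds.subset(order[n_train:]),
    }


@pytest.fixture(scope="session")
def trained(pipeline):
    vocab = pipeline["vocab"]
    spec = build_spec(2, vocab_size=vocab.size, max_positions=CAPACITY)
    model, trace = pretrain(
        pipeline["train"],
        spec,
        MaskingConfig(seed=1),
        TrainConfig(max_lr=2e-3, epochs=20, batch_size=32, seed=0),
    )
    return {"model": model, "trace": trace, "spec": spec}


@pytest.fixture(scope="session")
def quantized(trained):
    return quantize_model(trained["model"], precision="nf4dq")
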