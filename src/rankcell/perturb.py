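"""In silico gene deletion and embedding cosine-shift analysis.

Deleting a gene means removing its token from the cell's rank value encoding
(later tokens move up one rank; CLS and EOS are preserved) and re-running
the forward pass.  Each remaining gene's sensitivity is the cosine shift
``1 - cos(original embedding, perturbed embedding)``, matched by gene
identity, not position.  Shifts are aggregated per gene across the selected
cells and predefined gene groups (e.g. the regulator's direct targets versus
housekeeping genes) are compared by two-sided rank-sum tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .embed import cosine_similarity
from .encoder import EncoderModel
from .tokenize import TokenizedDataset, TokenVocabulary

__all__ = [
    "PerturbationPlan",
    "PerturbationResult",
    "in_silico_delete",
    "run_deletion",
    "aggregate_shifts",
    "compare_gene_groups",
    "perturbation_workload",
]


@dataclass(frozen=True)
class PerturbationPlan:
    """Which gene(s) to delete and in which cells.

    ``detection_quantile`` restricts the *affected* genes reported to those
    in the top quantile span of detection counts across the selected cells
    (0.5 keeps the top two quartiles; 0 keeps everything).
    """

    genes: tuple[int, ...] = ()  # gene tokens to delete, one at a time
    genome_wide: bool = False
    detection_quantile: float = 0.5
    max_cells: int | None = None
    seed: int = 0


@dataclass
class PerturbationResult:
    """Aggregated cosine shifts and group-comparison records."""

    per_gene: pd.DataFrame  # columns: gene_token, mean_shift, n_cells
    deleted_gene: int
    log: dict = field(default_factory=dict)
    group_stats: dict = field(default_factory=dict)


def _embed_cell(model: EncoderModel, tokens: np.ndarray, layer_tag: str) -> np.ndarray:
    ids = tokens[None, :]
    lengths = np.array([len(tokens)])
    hs = model.forward_hidden(ids, lengths, train=False)
    return model.hidden_at(hs, layer_tag)[0]


def in_silico_delete(
    tokens: np.ndarray,
    gene: int,
    model: EncoderModel,
    layer_tag: str = "second_to_last",
) -> dict[int, float]:
    """Delete one gene from one cell's encoding; return per-gene cosine shifts.

    The perturbed encoding is the original with exactly the one gene token
    removed.  Shift for each remaining gene g is ``1 - cos(h_g, h'_g)`` with
    embeddings matched by gene identity across the two forward passes.
    """
    tokens = np.asarray(tokens)
    pos = np.flatnonzero(tokens == gene)
    if len(pos) == 0:
        raise ValueError(f"gene token {gene} not present in the encoding")
    perturbed = np.delete(tokens, pos[0])
    h_orig = _embed_cell(model, tokens, layer_tag)
    h_pert = _embed_cell(model, perturbed, layer_tag)
    orig_pos = {int(t): i for i, t in enumerate(tokens)}
    shifts: dict[int, float] = {}
    for i, t in enumerate(perturbed):
        t = int(t)
        if t < TokenVocabulary.N_SPECIAL or t == gene:
            continue
        shifts[t] = 1.0 - cosine_similarity(h_orig[orig_pos[t]], h_pert[i])
    return shifts


def run_deletion(
    model: EncoderModel,
    dataset: TokenizedDataset,
    plan: PerturbationPlan,
    gene: int | None = None,
    layer_tag: str = "second_to_last",
) -> PerturbationResult:
    """Apply one gene's deletion across the cells selected by the plan."""
    if gene is None:
        if len(plan.genes) != 1:
            raise ValueError("specify the gene to delete (plan lists several)")
        gene = plan.genes[0]
    rng = np.random.default_rng(plan.seed)
    cells = [i for i, t in enumerate(dataset.tokens) if gene in t]
    if plan.max_cells is not None and len(cells) > plan.max_cells:
        cells = list(rng.choice(cells, size=plan.max_cells, replace=False))
    if not cells:
        return PerturbationResult(
            per_gene=pd.DataFrame(columns=["gene_token", "mean_shift", "n_cells"]),
            deleted_gene=int(gene),
            log={"reason": f"gene token {gene} absent from all selected cells", "n_cells": 0},
        )
    per_cell = [in_silico_delete(dataset.tokens[i], gene, model, layer_tag) for i in cells]
    result = aggregate_shifts(per_cell, plan, dataset, cells)
    result.deleted_gene = int(gene)
    result.log["n_cells"] = len(cells)
    return result


def aggregate_shifts(
    per_cell: list[dict[int, float]],
    plan: PerturbationPlan,
    dataset: TokenizedDataset | None = None,
    cell_indices: list[int] | None = None,
) -> PerturbationResult:
    """Mean shift per affected gene over the cells where it was present.

    The detection-quantile filter keeps genes whose detection count (over
    the processed cells) lies at or above the configured quantile of the
    affected genes' detection distribution.
    """
    if not per_cell:
        raise ValueError("no per-cell results to aggregate")
    acc: dict[int, list[float]] = {}
    for shifts in per_cell:
        for g, s in shifts.items():
            acc.setdefault(g, []).append(s)
    detections = {g: len(v) for g, v in acc.items()}
    kept = set(acc)
    if plan.detection_quantile > 0 and len(detections) > 1:
        thresh = float(np.quantile(list(detections.values()), plan.detection_quantile))
        kept = {g for g, n in detections.items() if n >= thresh}
    rows = [
        {"gene_token": g, "mean_shift": float(np.mean(acc[g])), "n_cells": detections[g]}
        for g in sorted(kept)
    ]
    df = pd.DataFrame(rows, columns=["gene_token", "mean_shift", "n_cells"])
    log = {
        "n_affected_genes": len(acc),
        "n_after_detection_filter": len(kept),
        "detection_quantile": plan.detection_quantile,
    }
    return PerturbationResult(per_gene=df, deleted_gene=-1, log=log)


def compare_gene_groups(result: PerturbationResult, groups: dict[str, set[int]]) -> dict:
    """Pairwise two-sided rank-sum tests on per-gene mean shifts by group."""
    if len(groups) < 2:
        raise ValueError("need at least 2 gene groups")
    shifts = result.per_gene.set_index("gene_token")["mean_shift"]
    samples: dict[str, np.ndarray] = {}
    for name, genes in groups.items():
        present = [g for g in genes if g in shifts.index]
        if not present:
            raise ValueError(f"group {name!r} has no genes with aggregated shifts")
        samples[name] = shifts.loc[present].to_numpy()
    stats: dict = {"medians": {k: float(np.median(v)) for k, v in samples.items()},
                   "n": {k: int(len(v)) for k, v in samples.items()},
                   "tests": {}}
    names = list(samples)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            method = "exact" if (len(samples[a]) <= 25 and len(samples[b]) <= 25) else "auto"
            res = scipy.stats.mannwhitneyu(
                samples[a], samples[b], alternative="two-sided", method=method
            )
            stats["tests"][f"{a}_vs_{b}"] = {"statistic": float(res.statistic), "p": float(res.pvalue)}
    return stats


def perturbation_workload(
    n_cells: int,
    genes_detected_per_cell,
    n_perturbations: int | None = None,
) -> int:
    """Forward-pass cell states needed for a deletion screen.

    Genome-wide (``n_perturbations=None``): each cell is processed once
    unperturbed plus once per detected gene, i.e. ``sum(1 + detected)``.
    A targeted plan with k applicable perturbations costs ``cells * (1+k)``.
    30,000 cells at 4,096 detected genes each gives 122,910,000 states.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be nonnegative")
    if n_cells == 0:
        return 0
    if n_perturbations is not None:
        if n_perturbations < 0:
            raise ValueError("n_perturbations must be nonnegative")
        return int(n_cells) * (1 + int(n_perturbations))
    det = np.asarray(genes_detected_per_cell)
    if det.ndim == 0:
        det = np.full(n_cells, int(det))
    if len(det) != n_cells:
        raise ValueError("genes_detected_per_cell length must equal n_cells")
    if (det < 0).any():
        raise ValueError("detected gene counts must be nonnegative")
    return int((1 + det).sum())
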