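"""Seeded synthetic single-cell count corpora with planted biological structure.

The generator emulates the statistical features the rank-value-encoding
tokenizer and the masked-learning encoder rely on:

* distinct per-cell-type expression programs (negative-binomial counts),
* ubiquitously high housekeeping genes with low relative dispersion,
* low-expression regulator genes with a cell-type on/off pattern and planted
  regulator -> target dependencies (target means multiplied by an effect size
  wherever the regulator is "on"),
* log-normal per-cell library size applied multiplicatively to the NB means,
* study / batch / platform / preservation metadata, with deliberately
  duplicated studies sharing a DOI so deduplication is exercisable,
* a malignant flag marking high-mutational-burden cells to exclude from the
  gene median dictionary.

Counts are held as a ``scipy.sparse`` CSR matrix (genes x cells); metadata as
pandas DataFrames.  Everything is deterministic given ``CorpusConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CorpusConfig",
    "BatchEffectConfig",
    "CountCorpus",
    "generate_corpus",
    "inject_batch_effects",
    "write_corpus",
    "read_corpus",
]

_DISEASES = ("healthy", "disease_a", "disease_b")


@dataclass(frozen=True)
class CorpusConfig:
    """Parameters of the synthetic corpus generator.

    Gene classes are disjoint: ``housekeeping_fraction`` of genes are
    housekeeping, ``regulator_count`` genes are regulators, roughly 40% are
    cell-type program genes and the remainder "other".  ``regulator_effect``
    multiplies target-gene means in cell types where the regulator is on.
    """

    n_genes: int = 200
    n_cells: int = 2000
    n_cell_types: int = 5
    n_tissues: int = 4
    tissue_proportions: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)
    housekeeping_fraction: float = 0.15
    regulator_count: int = 6
    targets_per_regulator: int = 12
    regulator_effect: float = 4.0
    n_studies: int = 6
    duplicate_study_pairs: int = 1
    malignant_fraction: float = 0.05
    depth_lognormal_params: tuple[float, float] = (math.log(1200.0), 0.6)
    nb_dispersion: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.tissue_proportions) - 1.0) > 1e-9:
            raise ValueError("tissue_proportions must sum to 1 within 1e-9")
        if len(self.tissue_proportions) != self.n_tissues:
            raise ValueError("tissue_proportions length must equal n_tissues")
        if not 0.0 <= self.housekeeping_fraction <= 1.0:
            raise ValueError("housekeeping_fraction must lie in [0, 1]")
        n_hk = int(round(self.housekeeping_fraction * self.n_genes))
        if n_hk + self.regulator_count > self.n_genes:
            raise ValueError(
                "overlapping gene-class fractions: housekeeping + regulators "
                f"claim {n_hk + self.regulator_count} of {self.n_genes} genes"
            )
        if self.n_cell_types < 1 or self.n_tissues < 1 or self.n_studies < 1:
            raise ValueError("n_cell_types, n_tissues, n_studies must be >= 1")
        if self.duplicate_study_pairs > self.n_studies:
            raise ValueError("more duplicate pairs than studies")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CorpusConfig":
        d = json.loads(text)
        for k in ("tissue_proportions", "depth_lognormal_params"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass(frozen=True)
class BatchEffectConfig:
    """Per-axis technical artifacts layered on top of a corpus.

    ``nucleus_dropout`` zeroes each detected entry of a nucleus-platform cell
    with the given Bernoulli rate (single-nucleus assays detect fewer genes);
    ``cell_dropout`` is the analogous rate for cell-platform cells.
    ``frozen_depth_scale`` / ``fresh_depth_scale`` multiply per-cell counts
    for the respective preservation label, with stochastic re-rounding of the
    fractional part.
    """

    nucleus_dropout: float = 0.0
    cell_dropout: float = 0.0
    frozen_depth_scale: float = 1.0
    fresh_depth_scale: float = 1.0
    seed: int = 0


@dataclass
class CountCorpus:
    """Sparse gene x cell counts plus cell- and gene-level metadata."""

    counts: sp.csr_matrix  # genes x cells, nonnegative integers
    cell_meta: pd.DataFrame  # indexed by cell_id
    gene_meta: pd.DataFrame  # indexed by gene_id
    config: CorpusConfig | None = None

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> None:
        if self.counts.shape != (len(self.gene_meta), len(self.cell_meta)):
            raise ValueError("counts dimensions do not match metadata tables")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be nonnegative")

    def subset_cells(self, mask: np.ndarray) -> "CountCorpus":
        """Return a new corpus restricted to cells where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return CountCorpus(
            counts=self.counts[:, mask].tocsr(),
            cell_meta=self.cell_meta.loc[mask].copy(),
            gene_meta=self.gene_meta.copy(),
            config=self.config,
        )

    def copy(self) -> "CountCorpus":
        return CountCorpus(
            self.counts.copy(), self.cell_meta.copy(), self.gene_meta.copy(), self.config
        )


def _assign_gene_classes(cfg: CorpusConfig, rng: np.random.Generator):
    n = cfg.n_genes
    n_hk = int(round(cfg.housekeeping_fraction * n))
    n_reg = cfg.regulator_count
    order = rng.permutation(n)
    hk = order[:n_hk]
    reg = order[n_hk : n_hk + n_reg]
    rest = order[n_hk + n_reg :]
    n_prog = int(round(0.4 * n))
    n_prog = min(n_prog, len(rest))
    prog = rest[:n_prog]
    other = rest[n_prog:]
    return hk, reg, prog, other


def generate_corpus(config: CorpusConfig) -> CountCorpus:
    """Draw a synthetic corpus. Deterministic given ``config`` (incl. seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, K = config.n_genes, config.n_cell_types

    hk, reg, prog, other = _assign_gene_classes(config, rng)

    # Mean expression per (gene, cell type), before depth scaling.
    mu = np.full((G, K), 0.0)
    mu[other, :] = 1.0
    mu[hk, :] = rng.uniform(30.0, 70.0, size=len(hk))[:, None]
    # Split program genes across cell types; elevated in their own type.
    if len(prog) and K:
        assignment = np.array_split(prog, K)
        for k, genes in enumerate(assignment):
            mu[genes, :] = 0.5
            mu[genes, k] = rng.uniform(6.0, 12.0, size=len(genes))
    # Regulators emulate transcription factors: a low basal level everywhere
    # (so their non-zero median stays small) and a high-end burst in the
    # cells where they switch on — which sends them to the top ranks of the
    # rank value encoding exactly when they are active.  Targets come from
    # the "other" class (flat mean across cell types), so the regulator
    # token, not the cell type, predicts their elevation.
    REG_BASAL, REG_ON = 0.8, 8.0
    reg_permissive = np.zeros((len(reg), K), dtype=bool)
    targets: dict[int, np.ndarray] = {}
    eligible = other if len(other) else prog
    for i, g in enumerate(reg):
        on_types = rng.choice(K, size=max(1, K // 2), replace=False)
        reg_permissive[i, on_types] = True
        mu[g, :] = REG_BASAL
        n_t = min(config.targets_per_regulator, len(eligible))
        tg = rng.choice(eligible, size=n_t, replace=False) if n_t else np.array([], int)
        targets[int(g)] = np.sort(tg)

    # Cell-level metadata.
    N = config.n_cells
    cell_type = rng.integers(0, K, size=N)
    tissue = rng.choice(config.n_tissues, size=N, p=np.asarray(config.tissue_proportions))
    n_base = config.n_studies
    study = rng.integers(0, n_base, size=N)
    malignant = rng.random(N) < config.malignant_fraction
    platform = np.where(rng.random(N) < 0.5, "cell", "nucleus")
    preservation = np.where(rng.random(N) < 0.5, "fresh", "frozen")

    study_doi = {s: f"10.9999/synth.{s:03d}" for s in range(n_base)}
    study_disease = {s: _DISEASES[s % len(_DISEASES)] for s in range(n_base)}

    depth_mu, depth_sigma = config.depth_lognormal_params
    lib = rng.lognormal(depth_mu, depth_sigma, size=N)
    phi = np.full(G, config.nb_dispersion)
    phi[hk] = config.nb_dispersion / 5.0  # low relative dispersion

    # Per-cell regulator states: on with probability 0.3 in permissive types,
    # so basal (off-state) detections dominate the non-zero median.
    reg_state = np.zeros((len(reg), N), dtype=bool)
    for i in range(len(reg)):
        permissive = reg_permissive[i, cell_type]
        reg_state[i] = permissive & (rng.random(N) < 0.3)

    counts = np.zeros((G, N), dtype=np.int64)
    for j in range(N):
        m = mu[:, cell_type[j]].copy()
        for i, g in enumerate(reg):
            if reg_state[i, j]:
                m[g] = REG_ON
                tg = targets[int(g)]
                # each target responds independently, so sibling targets are
                # an imperfect proxy for the regulator's state
                hit = rng.random(len(tg)) < 0.6
                m[tg[hit]] *= config.regulator_effect
        m *= lib[j] / max(m.sum(), 1e-12)
        # Gamma-Poisson mixture == NB with var = m + phi m^2.
        lam = rng.gamma(shape=1.0 / phi, scale=m * phi)
        counts[:, j] = rng.poisson(lam)

    cell_ids = [f"cell_{j:05d}" for j in range(N)]
    cell_meta = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "cell_type": [f"type_{k}" for k in cell_type],
            "tissue": [f"tissue_{t}" for t in tissue],
            "study": [f"study_{s:03d}" for s in study],
            "doi": [study_doi[s] for s in study],
            "batch": [f"batch_{s:03d}" for s in study],
            "platform": platform,
            "preservation": preservation,
            "malignant": malignant,
            "disease": [study_disease[s] for s in study],
        }
    ).set_index("cell_id", drop=False)
    # latent per-cell regulator states, exposed for planted-structure checks
    for i, g in enumerate(reg):
        cell_meta[f"regulator_on:ENSG{g:08d}"] = reg_state[i]

    # Duplicate studies: exact copies of an existing study's cells under a new
    # accession sharing the same DOI (deduplication is then checkable by
    # equality).
    dup_blocks = []
    dup_meta = []
    for p in range(config.duplicate_study_pairs):
        src = p % n_base
        sel = np.flatnonzero(study == src)
        if not len(sel):
            continue
        acc = f"study_{n_base + p:03d}"
        dup_blocks.append(counts[:, sel])
        dm = cell_meta.iloc[sel].copy()
        dm["study"] = acc
        dm["batch"] = f"batch_{n_base + p:03d}"
        dm["cell_id"] = [f"cell_dup{p}_{i:05d}" for i in range(len(sel))]
        dm = dm.set_index("cell_id", drop=False)
        dup_meta.append(dm)
    if dup_blocks:
        counts = np.concatenate([counts] + dup_blocks, axis=1)
        cell_meta = pd.concat([cell_meta] + dup_meta)

    gene_ids = [f"ENSG{g:08d}" for g in range(G)]
    gene_class = np.array(["other"] * G, dtype=object)
    gene_class[hk] = "housekeeping"
    gene_class[reg] = "regulator"
    gene_class[prog] = "program"
    regulator_of = ["" for _ in range(G)]
    for g, tg in targets.items():
        regulator_of[g] = ",".join(gene_ids[t] for t in tg)
    protein_coding = rng.random(G) < 0.9
    gene_meta = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "token_id": -1,  # assigned by the vocabulary builder
            "protein_coding": protein_coding,
            "class": gene_class,
            "regulator_of": regulator_of,
        }
    ).set_index("gene_id", drop=False)

    out = CountCorpus(
        counts=sp.csr_matrix(counts), cell_meta=cell_meta, gene_meta=gene_meta, config=config
    )
    out.validate()
    return out


def inject_batch_effects(corpus: CountCorpus, effects: BatchEffectConfig) -> CountCorpus:
    """Layer depth-scaling and detection-dropout artifacts onto a corpus.

    Returns a new corpus; the input is untouched.  Depth scaling multiplies a
    labeled group's counts and re-rounds stochastically so totals change by
    the scale factor in expectation; dropout zeroes detected entries per gene
    per cell with the platform's Bernoulli rate.
    """
    rng = np.random.default_rng(effects.seed)
    dense = np.asarray(corpus.counts.todense(), dtype=np.float64)
    meta = corpus.cell_meta

    for label, scale in (("frozen", effects.frozen_depth_scale), ("fresh", effects.fresh_depth_scale)):
        if scale != 1.0:
            cols = np.flatnonzero((meta["preservation"] == label).to_numpy())
            dense[:, cols] *= scale
    # stochastic re-rounding keeps expectations exact for fractional scales
    frac = dense - np.floor(dense)
    dense = np.floor(dense) + (rng.random(dense.shape) < frac)

    for label, rate in (("nucleus", effects.nucleus_dropout), ("cell", effects.cell_dropout)):
        if rate > 0.0:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"dropout rate for platform '{label}' outside [0, 1]")
            cols = np.flatnonzero((meta["platform"] == label).to_numpy())
            keep = rng.random((dense.shape[0], len(cols))) >= rate
            dense[:, cols] *= keep

    return CountCorpus(
        counts=sp.csr_matrix(dense.astype(np.int64)),
        cell_meta=meta.copy(),
        gene_meta=corpus.gene_meta.copy(),
        config=corpus.config,
    )


# --------------------------------------------------------------------------
# Disk format: Matrix Market counts + TSV metadata + JSON sidecar.

def write_corpus(corpus: CountCorpus, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "counts.mtx"), corpus.counts.tocoo(), field="integer")
    corpus.cell_meta.to_csv(outdir / "cell_meta.tsv", sep="\t", index=False)
    corpus.gene_meta.to_csv(outdir / "gene_meta.tsv", sep="\t", index=False)
    sidecar = {"config": None if corpus.config is None else dataclasses.asdict(corpus.config)}
    (outdir / "corpus.json").write_text(json.dumps(sidecar, indent=1))


def read_corpus(indir: str | Path) -> CountCorpus:
    indir = Path(indir)
    counts = sp.csr_matrix(scipy.io.mmread(str(indir / "counts.mtx")))
    cell_meta = pd.read_csv(indir / "cell_meta.tsv", sep="\t").set_index("cell_id", drop=False)
    gene_meta = pd.read_csv(
        indir / "gene_meta.tsv", sep="\t", keep_default_na=False, na_values=[]
    ).set_index("gene_id", drop=False)
    gene_meta["protein_coding"] = gene_meta["protein_coding"].astype(bool)
    cfg = None
    sidecar = indir / "corpus.json"
    if sidecar.exists():
        d = json.loads(sidecar.read_text())
        if d.get("config"):
            cfg = CorpusConfig.from_json(json.dumps(d["config"]))
    out = CountCorpus(counts=counts, cell_meta=cell_meta, gene_meta=gene_meta, config=cfg)
    out.validate()
    return out
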