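"""NF4 blockwise quantization, double quantization, int8 inference, LoRA.

4-bit NormalFloat (NF4) is a 16-level codebook built from standard-normal
quantiles with an exact zero level and endpoints at +/-1; weights are
quantized per block of B1 elements against the block's absolute maximum.
Double quantization compresses the per-block scales themselves: scales are
offset by their tensor-wide mean and symmetrically quantized to 8-bit in
blocks of B2 with one full-precision second-level scale each, saving
``32/B1 - (8/B1 + 32/(B1*B2))`` bits per parameter (0.373, i.e. ~0.4, at
the B1=64 / B2=256 defaults).

8-bit inference quantization is symmetric per-output-unit absolute-maximum
rounding, with no low-rank matrices involved.  LoRA adds trainable low-rank
updates ``(alpha/r) * A @ B`` to frozen (optionally quantized) projections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.stats

from .encoder import EncoderModel

__all__ = [
    "NF4Codebook",
    "QuantizedTensor",
    "Int8Tensor",
    "build_nf4_codebook",
    "quantize_blockwise",
    "dequantize_blockwise",
    "quantize_model",
    "attach_lora",
    "lora_trainable_parameters",
    "memory_footprint",
    "quantization_fidelity",
    "save_quantized",
    "load_quantized",
    "pack_codes",
    "unpack_codes",
]

#: Default block sizes: B1 elements share one NF4 scale; B2 scales share one
#: second-level 8-bit scale.
DEFAULT_B1 = 64
DEFAULT_B2 = 256

_NF4_OFFSET = 0.9677083  # tail probability anchor of the reference construction


@dataclass(frozen=True)
class NF4Codebook:
    levels: np.ndarray  # 16 strictly increasing values in [-1, 1]

    @property
    def zero_index(self) -> int:
        return int(np.flatnonzero(self.levels == 0.0)[0])

    @property
    def max_gap(self) -> float:
        return float(np.diff(self.levels).max())

    def content_hash(self) -> str:
        import hashlib

        return hashlib.sha256(self.levels.tobytes()).hexdigest()[:16]


def build_nf4_codebook() -> NF4Codebook:
    """16 levels: normalized standard-normal quantiles with an exact zero.

    Eight positive quantiles are taken at probabilities evenly spaced from
    the offset down to 1/2, seven negative ones likewise (the asymmetry
    makes room for the exact zero), and all are normalized by the largest
    magnitude so the endpoints are exactly -1 and +1.
    """
    pos = scipy.stats.norm.ppf(np.linspace(_NF4_OFFSET, 0.5, 9))[:-1]
    neg = -scipy.stats.norm.ppf(np.linspace(_NF4_OFFSET, 0.5, 8))[:-1]
    levels = np.sort(np.concatenate([neg, [0.0], pos]))
    levels = levels / np.abs(levels).max()
    levels[np.argmin(np.abs(levels))] = 0.0  # keep the zero exact
    return NF4Codebook(levels=levels)


@dataclass
class QuantizedTensor:
    """Blockwise NF4 codes with plain or nested (double-quantized) scales."""

    codes: np.ndarray  # uint8 in 0..15, flat
    shape: tuple[int, ...]
    block_size: int
    levels: np.ndarray
    scales: np.ndarray | None = None  # full-precision scales (no nesting)
    scale_codes: np.ndarray | None = None  # int8 codes of centered scales
    scale_block_size: int | None = None  # B2
    second_scales: np.ndarray | None = None  # one per B2-block
    scale_mean: float = 0.0

    @property
    def n_elements(self) -> int:
        return int(np.prod(self.shape))

    @property
    def n_blocks(self) -> int:
        return -(-self.n_elements // self.block_size)

    def reconstructed_scales(self) -> np.ndarray:
        if self.scales is not None:
            return self.scales
        s2 = np.repeat(self.second_scales, self.scale_block_size)[: len(self.scale_codes)]
        return self.scale_codes.astype(np.float64) / 127.0 * s2 + self.scale_mean

    def dequantize(self) -> np.ndarray:
        if self.codes.min(initial=0) < 0 or self.codes.max(initial=0) > 15:
            raise ValueError("corrupted 4-bit code outside 0..15")
        vals = self.levels[self.codes]
        scales = np.repeat(self.reconstructed_scales(), self.block_size)[: self.n_elements]
        return (vals * scales).reshape(self.shape)


@dataclass
class Int8Tensor:
    """Symmetric per-output-unit absolute-maximum 8-bit quantization."""

    codes: np.ndarray  # int8, same shape as the weight
    scales: np.ndarray  # one per output unit (last axis)

    def dequantize(self) -> np.ndarray:
        return self.codes.astype(np.float64) * self.scales


def quantize_blockwise(
    values: np.ndarray,
    codebook: NF4Codebook | None = None,
    block_size: int = DEFAULT_B1,
    double_quantize: bool = False,
    scale_block_size: int = DEFAULT_B2,
) -> QuantizedTensor:
    """Quantize a tensor to NF4 codes, optionally double-quantizing the scales.

    Per block of ``block_size`` elements the scale is the absolute maximum;
    each value/scale maps to the nearest codebook level with ties going to
    the lower code index.  All-zero blocks get scale 0 and the zero level.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    values = np.asarray(values, dtype=np.float64)
    if not np.isfinite(values).all():
        raise ValueError("cannot quantize non-finite values")
    cb = codebook or build_nf4_codebook()
    flat = values.ravel()
    n = flat.size
    n_blocks = -(-n // block_size)
    padded = np.zeros(n_blocks * block_size)
    padded[:n] = flat
    blocks = padded.reshape(n_blocks, block_size)
    scales = np.abs(blocks).max(axis=1)
    safe = np.where(scales > 0, scales, 1.0)
    normalized = blocks / safe[:, None]
    # nearest level; argmin returns the first (lower) index on exact ties
    codes = np.abs(normalized[:, :, None] - cb.levels[None, None, :]).argmin(axis=2)
    codes[scales == 0] = cb.zero_index
    codes = codes.astype(np.uint8).ravel()[:n]

    qt = QuantizedTensor(
        codes=codes, shape=values.shape, block_size=block_size, levels=cb.levels
    )
    if not double_quantize:
        qt.scales = scales
        return qt
    mean = float(scales.mean())
    centered = scales - mean
    n_sb = -(-len(centered) // scale_block_size)
    cpad = np.zeros(n_sb * scale_block_size)
    cpad[: len(centered)] = centered
    sblocks = cpad.reshape(n_sb, scale_block_size)
    second = np.abs(sblocks).max(axis=1)
    ssafe = np.where(second > 0, second, 1.0)
    scodes = np.clip(np.round(sblocks / ssafe[:, None] * 127.0), -127, 127).astype(np.int8)
    qt.scale_codes = scodes.ravel()[: len(centered)]
    qt.scale_block_size = scale_block_size
    qt.second_scales = second
    qt.scale_mean = mean
    return qt


def dequantize_blockwise(q: QuantizedTensor, codebook: NF4Codebook | None = None) -> np.ndarray:
    if codebook is not None and not np.array_equal(codebook.levels, q.levels):
        raise ValueError("codebook does not match the tensor's levels")
    return q.dequantize()


def quantize_int8(values: np.ndarray) -> Int8Tensor:
    values = np.asarray(values, dtype=np.float64)
    absmax = np.abs(values).max(axis=tuple(range(values.ndim - 1)))
    scales = np.where(absmax > 0, absmax / 127.0, 1.0)
    codes = np.clip(np.round(values / scales), -127, 127).astype(np.int8)
    return Int8Tensor(codes=codes, scales=scales)


_LINEAR_SUFFIXES = ("Wq", "Wk", "Wv", "Wo", "W1", "W2")


def linear_weight_names(spec) -> list[str]:
    return [f"layer{i}.{w}" for i in range(spec.layers) for w in _LINEAR_SUFFIXES]


def quantize_model(
    model: EncoderModel,
    precision: str = "nf4dq",
    targets: list[str] | None = None,
    block_size: int = DEFAULT_B1,
    scale_block_size: int = DEFAULT_B2,
) -> EncoderModel:
    """Return a copy whose linear projection weights are quantized.

    ``precision="nf4"``/``"nf4dq"`` applies blockwise NF4 (with double
    quantization for ``nf4dq``); ``"int8"`` applies symmetric per-output-unit
    8-bit quantization.  Embeddings, biases and layer norms stay in full
    precision.  The forward pass dequantizes on the fly; the architecture is
    unchanged.
    """
    if precision not in ("nf4", "nf4dq", "int8"):
        raise ValueError("precision must be one of 'nf4', 'nf4dq', 'int8'")
    names = linear_weight_names(model.spec)
    if targets is not None:
        names = [n for n in names if any(t in n for t in targets)]
        if not names:
            raise ValueError(f"target filter {targets!r} matches no linear weights")
    out = model.copy()
    cb = build_nf4_codebook()
    for name in names:
        w = out.params[name]
        if precision == "int8":
            out.qweights[name] = quantize_int8(w)
        else:
            out.qweights[name] = quantize_blockwise(
                w, cb, block_size=block_size,
                double_quantize=(precision == "nf4dq"),
                scale_block_size=scale_block_size,
            )
    return out


def attach_lora(
    model: EncoderModel,
    targets: tuple[str, ...] = ("Wq", "Wk", "Wv"),
    r: int = 8,
    alpha: float = 16.0,
    seed: int = 0,
) -> EncoderModel:
    """Attach low-rank adapters to the targeted projections and freeze the base.

    A is zero-mean Gaussian, B is zero-initialized, so the adapter-equipped
    forward equals the base forward until training moves B.  Published task
    defaults: rank 128 / alpha 256 for gene-level tasks, rank 32 / alpha 64
    for cell-level tasks (desk-scale models use proportionally smaller ranks).
    """
    if r < 1:
        raise ValueError("rank must be >= 1")
    out = model.copy()
    rng = np.random.default_rng(seed)
    names = [n for n in linear_weight_names(model.spec) if any(n.endswith(t) for t in targets)]
    if not names:
        raise ValueError(f"no linear weights match targets {targets!r}")
    for name in names:
        d_in, d_out = out.params[name].shape
        if r >= min(d_in, d_out):
            raise ValueError(f"rank {r} not below min dimension {min(d_in, d_out)} of {name}")
        out.adapters[name] = {
            "A": rng.normal(0.0, model.spec.init_std, size=(d_in, r)),
            "B": np.zeros((r, d_out)),
            "r": r,
            "alpha": float(alpha),
        }
    out.frozen_base = True
    return out


def lora_trainable_parameters(model: EncoderModel) -> int:
    """Sum of r*(d_in + d_out) over adapters (2*N*r for square targets)."""
    return sum(a["A"].size + a["B"].size for a in model.adapters.values())


@dataclass(frozen=True)
class MemoryFootprint:
    bits_per_param_plain: float
    bits_per_param_nested: float
    saving_bits_per_param: float
    per_tensor_bits: dict
    total_bits: float


def memory_footprint(
    block_size: int = DEFAULT_B1,
    scale_block_size: int = DEFAULT_B2,
    tensor_sizes: dict | None = None,
) -> MemoryFootprint:
    """Analytic NF4 storage accounting in bits per parameter.

    Without nesting each B1-block carries one 32-bit scale: 4 + 32/B1 bits
    per parameter.  With double quantization the scale is an 8-bit code plus
    a shared 32-bit second-level scale per B2 scales: 4 + 8/B1 + 32/(B1*B2).
    """
    plain = 4.0 + 32.0 / block_size
    nested = 4.0 + 8.0 / block_size + 32.0 / (block_size * scale_block_size)
    per_tensor = {}
    total = 0.0
    for name, n in (tensor_sizes or {}).items():
        per_tensor[name] = nested * n
        total += nested * n
    return MemoryFootprint(
        bits_per_param_plain=plain,
        bits_per_param_nested=nested,
        saving_bits_per_param=plain - nested,
        per_tensor_bits=per_tensor,
        total_bits=total,
    )


def quantization_fidelity(
    full_model: EncoderModel,
    quant_model: EncoderModel,
    dataset,
    cell_meta=None,
    layer_tag: str = "second_to_last",
    n_pairs: int = 100,
    seed: int = 0,
) -> dict:
    """Paired cosine similarity of full vs quantized embeddings, in context.

    For each (gene, cell) the similarity between the two models' embeddings
    is compared against (i) the full model's same-gene similarity across
    different cell types and (ii) its different-gene similarity, via
    two-sided rank-sum tests — quantization noise should be negligible next
    to biological context.
    """
    from .embed import cosine_similarity, extract_gene_embeddings

    if full_model.spec != quant_model.spec:
        raise ValueError("models differ in architecture; fidelity comparison undefined")
    ef = extract_gene_embeddings(full_model, dataset, layer_tag)
    eq = extract_gene_embeddings(quant_model, dataset, layer_tag)
    rng = np.random.default_rng(seed)
    paired = np.array(
        [cosine_similarity(ef.vectors[i], eq.vectors[i]) for i in range(len(ef))]
    )

    meta = cell_meta if cell_meta is not None else dataset.cell_meta
    meta = meta.set_index("cell_id") if "cell_id" in meta.columns else meta
    idx = ef.index.join(meta[["cell_type"]], on="cell_id")
    arms = {"full_vs_quantized_same_gene_same_cell": paired}

    cross, diff = [], []
    by_gene = {g: grp.index.to_numpy() for g, grp in idx.groupby("gene_token")}
    genes = list(by_gene)
    ctypes = idx["cell_type"].to_numpy()
    tries = 0
    while len(cross) < n_pairs and tries < 100 * n_pairs:
        tries += 1
        rows = by_gene[genes[rng.integers(len(genes))]]
        if len(rows) < 2:
            continue
        i, j = rng.choice(rows, size=2, replace=False)
        if ctypes[i] != ctypes[j]:
            cross.append(cosine_similarity(ef.vectors[i], ef.vectors[j]))
    for _ in range(n_pairs):
        i, j = rng.choice(len(ef), size=2, replace=False)
        if idx["gene_token"].iloc[i] != idx["gene_token"].iloc[j]:
            diff.append(cosine_similarity(ef.vectors[i], ef.vectors[j]))
    if cross:
        arms["same_gene_different_cell_type"] = np.array(cross)
    if diff:
        arms["different_gene"] = np.array(diff)

    tests = {}
    names = list(arms)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            res = scipy.stats.mannwhitneyu(arms[a], arms[b], alternative="two-sided")
            tests[f"{a}_vs_{b}"] = {"statistic": float(res.statistic), "p": float(res.pvalue)}
    medians = {k: float(np.median(v)) for k, v in arms.items()}
    return {"arms": arms, "medians": medians, "tests": tests}


# ---------------------------------------------------------------------------
# Serialization: packed 4-bit codes, two per byte (little end first)


def pack_codes(codes: np.ndarray) -> np.ndarray:
    c = np.asarray(codes, dtype=np.uint8)
    if c.size % 2:
        c = np.concatenate([c, np.zeros(1, dtype=np.uint8)])
    return (c[0::2] | (c[1::2] << 4)).astype(np.uint8)


def unpack_codes(packed: np.ndarray, n: int) -> np.ndarray:
    p = np.asarray(packed, dtype=np.uint8)
    out = np.empty(p.size * 2, dtype=np.uint8)
    out[0::2] = p & 0x0F
    out[1::2] = p >> 4
    return out[:n]


def save_quantized(model: EncoderModel, outdir: str | Path) -> None:
    """Quantized checkpoint: packed codes + scales + full-precision leftovers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    manifest: dict = {"spec": json.loads(model.spec.to_json()), "tensors": {}}
    for name, qt in model.qweights.items():
        key = name.replace(".", "__")
        if isinstance(qt, Int8Tensor):
            arrays[f"{key}__int8"] = qt.codes
            arrays[f"{key}__int8_scales"] = qt.scales
            manifest["tensors"][name] = {"kind": "int8"}
            continue
        arrays[f"{key}__codes"] = pack_codes(qt.codes)
        entry = {
            "kind": "nf4",
            "shape": list(qt.shape),
            "block_size": qt.block_size,
            "n_codes": int(qt.codes.size),
        }
        if qt.scales is not None:
            arrays[f"{key}__scales"] = qt.scales.astype(np.float32)
        else:
            arrays[f"{key}__scale_codes"] = qt.scale_codes
            arrays[f"{key}__second_scales"] = qt.second_scales.astype(np.float32)
            entry["scale_block_size"] = qt.scale_block_size
            entry["scale_mean"] = qt.scale_mean
        manifest["tensors"][name] = entry
    for name, w in model.params.items():
        if name not in model.qweights:
            arrays[f"fp__{name.replace('.', '__')}"] = w
    cb = build_nf4_codebook()
    manifest["codebook_hash"] = cb.content_hash()
    np.savez(outdir / "quantized.npz", **arrays)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_quantized(indir: str | Path) -> EncoderModel:
    from .encoder import EncoderSpec

    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    spec = EncoderSpec(**manifest["spec"])
    cb = build_nf4_codebook()
    if manifest["codebook_hash"] != cb.content_hash():
        raise ValueError("codebook hash mismatch in quantized checkpoint")
    with np.load(indir / "quantized.npz") as z:
        arrays = {k: z[k] for k in z.files}
    params = {}
    for k, v in arrays.items():
        if k.startswith("fp__"):
            params[k[4:].replace("__", ".")] = v
    model = EncoderModel(spec, params=None)
    # overwrite initialized params with stored full-precision tensors
    for name, w in params.items():
        model.params[name] = w
    for name, entry in manifest["tensors"].items():
        key = name.replace(".", "__")
        if entry["kind"] == "int8":
            model.qweights[name] = Int8Tensor(
                codes=arrays[f"{key}__int8"], scales=arrays[f"{key}__int8_scales"]
            )
            continue
        qt = QuantizedTensor(
            codes=unpack_codes(arrays[f"{key}__codes"], entry["n_codes"]),
            shape=tuple(entry["shape"]),
            block_size=entry["block_size"],
            levels=cb.levels,
        )
        if f"{key}__scales" in arrays:
            qt.scales = arrays[f"{key}__scales"]
        else:
            qt.scale_codes = arrays[f"{key}__scale_codes"]
            qt.second_scales = arrays[f"{key}__second_scales"]
            qt.scale_block_size = entry["scale_block_size"]
            qt.scale_mean = entry["scale_mean"]
        model.qweights[name] = qt
    return model
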