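"""Post-training truncated-SVD compression of convolution weight matrices.

A trained model's storage is dominated by a handful of large weight
matrices.  Each such matrix W (m x n) factorises as W = U S V^T; keeping
only the leading k singular triplets gives the best rank-k approximation
W' = U' S' V'^T (Eckart-Young) and replaces m*n stored floats by
m*k + k + k*n.  Compression is applied after training and changes only
what is stored on disk: reconstructing W' yields a model with the exact
same architecture and parameter count.

Policy (matching the published procedure): the first three encoder
blocks are skipped — they hold high-detail features and few parameters —
and every remaining convolution weight matrix is factorised at rank
k = 4.  Biases and batch-norm parameters are always stored raw, as is
any matrix for which factorisation would not reduce storage
(m*k + k + k*n >= m*n).

Matrix views of convolution tensors: a dense (kh, kw, Cin, Cout) kernel
is reshaped to (kh*kw*Cin, Cout) in C order; for separable convolutions
only the (Cin, Cout) pointwise matrix is factorised, since the depthwise
kernel is already minimal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .archspec import ModelSpec, count_parameters
from .nn import check_params

__all__ = [
    "SVDFactors",
    "CompressedArchive",
    "StorageReport",
    "svd_truncate",
    "reconstruct",
    "compress_model",
    "reconstruct_model",
    "storage_report",
    "save_weights",
    "load_weights",
    "save_archive",
    "load_archive",
]


@dataclass
class SVDFactors:
    """Truncated factorisation of an m x n matrix at rank k."""

    U_trunc: np.ndarray  # (m, k)
    S_trunc: np.ndarray  # (k,) non-increasing, >= 0
    Vt_trunc: np.ndarray  # (k, n)

    @property
    def k(self) -> int:
        return int(self.S_trunc.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return int(self.U_trunc.shape[0]), int(self.Vt_trunc.shape[1])

    @property
    def stored_floats(self) -> int:
        m, n = self.shape
        return m * self.k + self.k + self.k * n


def svd_truncate(values: np.ndarray, k: int) -> SVDFactors:
    """Top-k singular triplets of a matrix.

    Singular-vector sign ambiguity is fixed by making the
    largest-magnitude entry of each left singular vector non-negative,
    so archives are bit-reproducible.
    """
    w = np.asarray(values)
    if w.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {w.shape}")
    if not np.all(np.isfinite(w)):
        raise ValueError("matrix contains non-finite values")
    m, n = w.shape
    if not 1 <= k <= min(m, n):
        raise ValueError(f"rank k={k} out of range for a {m}x{n} matrix")
    u, s, vt = np.linalg.svd(w, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # deterministic sign convention
    flip = u[np.abs(u).argmax(axis=0), np.arange(k)] < 0
    u = np.where(flip, -u, u)
    vt = np.where(flip[:, None], -vt, vt)
    return SVDFactors(
        U_trunc=np.ascontiguousarray(u, dtype=w.dtype),
        S_trunc=np.ascontiguousarray(s, dtype=w.dtype),
        Vt_trunc=np.ascontiguousarray(vt, dtype=w.dtype),
    )


def reconstruct(factors: SVDFactors) -> np.ndarray:
    """W' = U' diag(S') V'^T, same shape as the source matrix."""
    u, s, vt = factors.U_trunc, factors.S_trunc, factors.Vt_trunc
    if u.shape[1] != s.shape[0] or vt.shape[0] != s.shape[0]:
        raise ValueError("inconsistent factor dimensions")
    return (u * s) @ vt


@dataclass
class CompressedArchive:
    """Per-layer storage: raw arrays or truncated factors.

    ``entries`` maps layer name -> {array name -> ndarray | SVDFactors}.
    ``manifest`` records stored-float counts per entry; ``k_used``
    records the rank policy the archive was produced with.
    """

    entries: dict[str, dict[str, object]]
    k_used: dict = field(default_factory=dict)

    @property
    def manifest(self) -> dict[str, int]:
        out = {}
        for lname, arrays in self.entries.items():
            total = 0
            for arr in arrays.values():
                total += arr.stored_floats if isinstance(arr, SVDFactors) else arr.size
            out[lname] = total
        return out

    @property
    def stored_floats(self) -> int:
        return sum(self.manifest.values())


def _encoder_block(layer_name: str) -> int | None:
    if layer_name.startswith("enc") and layer_name[3].isdigit():
        return int(layer_name[3])
    return None


def _encoder_layer_index(spec: ModelSpec, layer_name: str) -> int | None:
    """1-based position of a convolution within the encoder, else None."""
    i = 0
    for layer in spec.layers:
        if layer.kind in ("conv2d", "separable_conv2d") and _encoder_block(layer.name):
            i += 1
            if layer.name == layer_name:
                return i
    return None


def _should_skip(spec: ModelSpec, name: str, skip_blocks: int, granularity: str) -> bool:
    if granularity == "blocks":
        block = _encoder_block(name)
        return block is not None and block <= skip_blocks
    if granularity == "layers":
        pos = _encoder_layer_index(spec, name)
        return pos is not None and pos <= skip_blocks
    raise ValueError(f"unknown skip granularity {granularity!r}")


def _worthwhile(m: int, n: int, k: int) -> bool:
    return m * k + k + k * n < m * n


def compress_model(
    params: dict,
    spec: ModelSpec,
    *,
    k: int = 4,
    skip_blocks: int = 3,
    skip_granularity: str = "blocks",
) -> CompressedArchive:
    """Compress a weight tree into a :class:`CompressedArchive`.

    Convolutions in the first ``skip_blocks`` encoder blocks, all
    biases, all batch-norm parameters and all depthwise kernels stay
    raw.  Every other convolution weight matrix is factorised at rank
    ``min(k, m, n)`` unless that would not reduce storage, in which
    case it falls back to raw storage.
    """
    check_params(spec, params)
    entries: dict[str, dict[str, object]] = {}
    for layer in spec.layers:
        if layer.name not in params:
            continue
        arrays = params[layer.name]
        entry: dict[str, object] = {}
        factorable = layer.kind in ("conv2d", "separable_conv2d") and not _should_skip(
            spec, layer.name, skip_blocks, skip_granularity
        )
        for key, arr in arrays.items():
            matrix_key = key in ("kernel", "pointwise")
            if factorable and matrix_key:
                if key == "kernel":
                    kh, kw, cin, cout = arr.shape
                    mat = arr.reshape(kh * kw * cin, cout)
                else:
                    mat = arr
                m, n = mat.shape
                k_eff = min(k, m, n)
                if _worthwhile(m, n, k_eff):
                    entry[key] = svd_truncate(mat, k_eff)
                else:
                    entry[key] = np.array(arr, copy=True)
            else:
                entry[key] = np.array(arr, copy=True)
        entries[layer.name] = entry
    return CompressedArchive(
        entries=entries,
        k_used={"k": k, "skip_blocks": skip_blocks, "skip_granularity": skip_granularity},
    )


def reconstruct_model(archive: CompressedArchive, spec: ModelSpec) -> dict:
    """Expand an archive back into a full weight tree (W' in place of W)."""
    params: dict[str, dict[str, np.ndarray]] = {}
    shapes = {layer.name: layer for layer in spec.layers}
    for lname, arrays in archive.entries.items():
        layer = shapes.get(lname)
        out: dict[str, np.ndarray] = {}
        for key, arr in arrays.items():
            if isinstance(arr, SVDFactors):
                mat = reconstruct(arr)
                if key == "kernel":
                    kh, kw = layer.kernel
                    mat = mat.reshape(kh, kw, layer.channels_in, layer.channels_out)
                out[key] = np.ascontiguousarray(mat, dtype=np.float32)
            else:
                out[key] = np.array(arr, copy=True)
        params[lname] = out
    check_params(spec, params)
    return params


@dataclass(frozen=True)
class StorageReport:
    archive_floats: int
    baseline_floats: int

    @property
    def savings_percent(self) -> float:
        return 100.0 * (1.0 - self.archive_floats / self.baseline_floats)


def storage_report(archive: CompressedArchive, baseline_floats) -> StorageReport:
    """Float-count storage savings of an archive against a baseline.

    ``baseline_floats`` may be an integer float count or a
    :class:`~tinyseg.archspec.ParameterReport` (whose total is used);
    the float count is the normative proxy for on-disc size.
    """
    if hasattr(baseline_floats, "total"):
        baseline_floats = baseline_floats.total
    return StorageReport(
        archive_floats=archive.stored_floats, baseline_floats=int(baseline_floats)
    )


def baseline_floats(spec: ModelSpec) -> int:
    """Stored floats of an uncompressed archive (= parameter count)."""
    return count_parameters(spec).total


# ---------------------------------------------------------------------------
# HDF5 persistence.  Raw arrays are stored under "<layer>/<key>";
# factored entries as "<layer>/<key>.U", ".S", ".Vt" plus a scalar ".k".


def save_weights(path, params: dict) -> None:
    with h5py.File(path, "w") as f:
        for lname, arrays in params.items():
            grp = f.create_group(lname)
            for key, arr in arrays.items():
                grp.create_dataset(key, data=arr)


def load_weights(path) -> dict:
    params: dict[str, dict[str, np.ndarray]] = {}
    with h5py.File(path, "r") as f:
        for lname, grp in f.items():
            params[lname] = {key: np.asarray(ds) for key, ds in grp.items()}
    return params


def save_archive(path, archive: CompressedArchive) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["k_used"] = json.dumps(archive.k_used)
        for lname, arrays in archive.entries.items():
            grp = f.create_group(lname)
            for key, arr in arrays.items():
                if isinstance(arr, SVDFactors):
                    grp.create_dataset(key + ".U", data=arr.U_trunc)
                    grp.create_dataset(key + ".S", data=arr.S_trunc)
                    grp.create_dataset(key + ".Vt", data=arr.Vt_trunc)
                    grp.create_dataset(key + ".k", data=arr.k)
                else:
                    grp.create_dataset(key, data=arr)


def load_archive(path) -> CompressedArchive:
    entries: dict[str, dict[str, object]] = {}
    with h5py.File(path, "r") as f:
        k_used = json.loads(f.attrs.get("k_used", "{}"))
        for lname, grp in f.items():
            entry: dict[str, object] = {}
            for key in grp:
                if key.endswith((".S", ".Vt", ".k")):
                    continue
                if key.endswith(".U"):
                    stem = key[:-2]
                    entry[stem] = SVDFactors(
                        U_trunc=np.asarray(grp[stem + ".U"]),
                        S_trunc=np.asarray(grp[stem + ".S"]),
                        Vt_trunc=np.asarray(grp[stem + ".Vt"]),
                    )
                else:
                    entry[key] = np.asarray(grp[key])
            entries[lname] = entry
    return CompressedArchive(entries=entries, k_used=k_used)
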