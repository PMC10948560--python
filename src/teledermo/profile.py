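"""DermoFeature Profiles and their multi-patient collations.

A DP is a 7x7 matrix carrying one lesion's seven scaled features on its
main diagonal; it is the compact transmissible unit replacing a dermoscopy
image. N DPs are collated into a DMpDP in one of three layouts:

* ``horizontal`` — an ordered list of 7x7 blocks embedded one by one with a
  spacing of ``mu`` carrier samples between them;
* ``diagonal``   — a 7N x 7N block-diagonal matrix;
* ``sequential`` — a (7R) x (7C) grid of blocks filled row-major, by
  convention one class per row (R = 4).

Capacity and sample-count arithmetic mirrors the published formulas: the
diagonal form needs ``49 N^2`` carrier samples; the sequential form is
quoted in the source's own "paper mode" as ``49 (N/2)^2`` (the convention
behind its published size table) while the grid actually embedded ("packed
mode") occupies ``49 R ceil(N/R)`` samples; the horizontal form needs
``49 M + mu (M - 1)`` with M = N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ScalingError
from .features import FeatureVector

BLOCK = 7  # side of one DP block

FORMS = ("horizontal", "diagonal", "sequential")


@dataclass
class DP:
    """One 7x7 diagonal profile matrix with its source identifier."""

    matrix: np.ndarray
    source_id: str

    @property
    def features(self) -> np.ndarray:
        """The seven diagonal values, in feature order."""
        return np.diag(self.matrix).copy()


@dataclass
class DMpDP:
    """Collation of N DPs in one of the three layouts.

    ``matrix`` holds the assembled payload for the diagonal and sequential
    forms; the horizontal form keeps the ordered ``blocks`` list plus its
    ``spacing`` and leaves ``matrix`` as None.
    """

    form: str
    n_dps: int
    dp_order: list[str]
    matrix: np.ndarray | None = None
    blocks: list[np.ndarray] | None = None
    spacing: int | None = None
    grid_rows: int | None = None
    grid_cols: int | None = None


def build_dp(fv: FeatureVector | np.ndarray, source_id: str) -> DP:
    """Align seven scaled features on the diagonal of a 7x7 matrix."""
    values = fv.values if isinstance(fv, FeatureVector) else np.asarray(
        fv, dtype=float)
    if values.shape != (BLOCK,):
        raise ParameterError("a DP needs exactly 7 features")
    if np.any(values < 0.0) or np.any(values > 1.0):
        raise ScalingError("scaled features must lie in [0, 1]")
    return DP(matrix=np.diag(values.astype(float)), source_id=source_id)


def assemble(dps: list[DP], form: str, spacing: int = 25,
             grid_rows: int = 4) -> DMpDP:
    """Collate DPs into one DMpDP payload."""
    if form not in FORMS:
        raise ParameterError(f"unknown form {form!r}")
    n = len(dps)
    if n < 1:
        raise ParameterError("need at least one DP")
    ids = [dp.source_id for dp in dps]
    if len(set(ids)) != n:
        raise ParameterError("duplicate source_ids in DMpDP")

    if form == "horizontal":
        if spacing < 0:
            raise ParameterError("spacing must be >= 0")
        return DMpDP(form=form, n_dps=n, dp_order=ids,
                     blocks=[dp.matrix.copy() for dp in dps], spacing=spacing)
    if form == "diagonal":
        mat = np.zeros((BLOCK * n, BLOCK * n))
        for k, dp in enumerate(dps):
            s = k * BLOCK
            mat[s:s + BLOCK, s:s + BLOCK] = dp.matrix
        return DMpDP(form=form, n_dps=n, dp_order=ids, matrix=mat)
    # sequential: row-major R x ceil(N/R) block grid, unused blocks zero
    if grid_rows < 1:
        raise ParameterError("grid_rows must be >= 1")
    cols = math.ceil(n / grid_rows)
    mat = np.zeros((BLOCK * grid_rows, BLOCK * cols))
    for k, dp in enumerate(dps):
        r, c = divmod(k, cols)
        mat[r * BLOCK:(r + 1) * BLOCK, c * BLOCK:(c + 1) * BLOCK] = dp.matrix
    return DMpDP(form=form, n_dps=n, dp_order=ids, matrix=mat,
                 grid_rows=grid_rows, grid_cols=cols)


def disassemble_matrix(matrix: np.ndarray | list[np.ndarray], form: str,
                       n_dps: int, dp_order: list[str] | None = None,
                       grid_rows: int | None = None) -> list[DP]:
    """Recover DPs from a (possibly noisy) payload matrix.

    Off-diagonal residue inside each 7x7 block is discarded: only the
    diagonal carries features.
    """
    if dp_order is None:
        dp_order = [f"dp{k}" for k in range(n_dps)]
    if len(dp_order) != n_dps:
        raise ParameterError("dp_order length does not match n_dps")

    def _clean(block: np.ndarray, sid: str) -> DP:
        if block.shape != (BLOCK, BLOCK):
            raise ParameterError("payload shape inconsistent with layout")
        return DP(matrix=np.diag(np.diag(block)), source_id=sid)

    if form == "horizontal":
        blocks = list(matrix)
        if len(blocks) != n_dps:
            raise ParameterError("payload shape inconsistent with layout")
        return [_clean(b, sid) for b, sid in zip(blocks, dp_order)]
    matrix = np.asarray(matrix, dtype=float)
    if form == "diagonal":
        if matrix.shape != (BLOCK * n_dps, BLOCK * n_dps):
            raise ParameterError("payload shape inconsistent with layout")
        return [_clean(matrix[k * BLOCK:(k + 1) * BLOCK,
                               k * BLOCK:(k + 1) * BLOCK], sid)
                for k, sid in enumerate(dp_order)]
    if form == "sequential":
        if grid_rows is None or grid_rows < 1:
            raise ParameterError("sequential layout needs grid_rows")
        cols = math.ceil(n_dps / grid_rows)
        if matrix.shape != (BLOCK * grid_rows, BLOCK * cols):
            raise ParameterError("payload shape inconsistent with layout")
        out = []
        for k, sid in enumerate(dp_order):
            r, c = divmod(k, cols)
            out.append(_clean(matrix[r * BLOCK:(r + 1) * BLOCK,
                                     c * BLOCK:(c + 1) * BLOCK], sid))
        return out
    raise ParameterError(f"unknown form {form!r}")


def disassemble(dmpdp: DMpDP) -> list[DP]:
    """Split a DMpDP back into its DPs, in ``dp_order``."""
    payload = dmpdp.blocks if dmpdp.form == "horizontal" else dmpdp.matrix
    return disassemble_matrix(payload, dmpdp.form, dmpdp.n_dps,
                              dmpdp.dp_order, dmpdp.grid_rows)


def required_samples(form: str, n: int, spacing: int = 25, grid_rows: int = 4,
                     mode: str = "paper") -> int:
    """Carrier samples needed to embed N DPs in the given layout.

    For the sequential form, ``mode='paper'`` reproduces the published
    L = 49 (N/2)^2 size arithmetic; ``mode='packed'`` gives the samples the
    R x ceil(N/R) grid actually occupies.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if form == "diagonal":
        return 49 * n * n
    if form == "sequential":
        if mode == "paper":
            return int(round(49 * (n / 2.0) ** 2))
        if mode == "packed":
            return 49 * grid_rows * math.ceil(n / grid_rows)
        raise ParameterError(f"unknown sequential mode {mode!r}")
    if form == "horizontal":
        if spacing < 0:
            raise ParameterError("spacing must be >= 0")
        return 49 * n + spacing * (n - 1)
    raise ParameterError(f"unknown form {form!r}")


def capacity(form: str, carrier_length: int, spacing: int = 25,
             grid_rows: int = 4) -> int:
    """Maximum number of DPs a carrier of the given length can hold.

    Follows the published arithmetic: diagonal capacity is
    floor(floor(sqrt(L)) / 7); sequential capacity divides the carrier over
    ``grid_rows`` 7-sample-wide class rows (floor(L / (R*7)) samples per
    DMpDP column) and fits floor(columns / 7) DPs per row slot.
    """
    if carrier_length < 49:
        return 0
    if form == "diagonal":
        return int(math.isqrt(carrier_length)) // BLOCK
    if form == "sequential":
        per_column = carrier_length // (grid_rows * BLOCK)
        return per_column // BLOCK
    if form == "horizontal":
        if spacing < 0:
            raise ParameterError("spacing must be >= 0")
        return (carrier_length + spacing) // (49 + spacing)
    raise ParameterError(f"unknown form {form!r}")


def serialized_size(n_dps: int, bytes_per_value: int = 8) -> int:
    """Transmission size of N DPs: 49 values per DP (392 bytes at 8-byte
    values)."""
    if n_dps < 1:
        raise ParameterError("n_dps must be >= 1")
    return n_dps * BLOCK * BLOCK * bytes_per_value


# ---------------------------------------------------------------------------
# serialization

def save_dmpdp(dmpdp: DMpDP, path) -> None:
    """Persist a DMpDP with its layout metadata (lossless npz container)."""
    payload = {}
    if dmpdp.form == "horizontal":
        for k, b in enumerate(dmpdp.blocks):
            payload[f"block_{k}"] = b
    else:
        payload["matrix"] = dmpdp.matrix
    np.savez(
        path, form=dmpdp.form, n_dps=dmpdp.n_dps,
        dp_order=np.array(dmpdp.dp_order),
        spacing=-1 if dmpdp.spacing is None else dmpdp.spacing,
        grid_rows=-1 if dmpdp.grid_rows is None else dmpdp.grid_rows,
        grid_cols=-1 if dmpdp.grid_cols is None else dmpdp.grid_cols,
        **payload)


def load_dmpdp(path) -> DMpDP:
    with np.load(path, allow_pickle=False) as z:
        form = str(z["form"])
        n = int(z["n_dps"])
        order = [str(s) for s in z["dp_order"]]
        spacing = int(z["spacing"])
        rows = int(z["grid_rows"])
        cols = int(z["grid_cols"])
        if form == "horizontal":
            blocks = [z[f"block_{k}"] for k in range(n)]
            matrix = None
        else:
            blocks, matrix = None, z["matrix"]
    return DMpDP(form=form, n_dps=n, dp_order=order, matrix=matrix,
                 blocks=blocks, spacing=None if spacing < 0 else spacing,
                 grid_rows=None if rows < 0 else rows,
                 grid_cols=None if cols < 0 else cols)


def preview_png(dmpdp: DMpDP, path) -> None:
    """Write an 8-bit grayscale preview of the payload matrix."""
    import imageio.v3 as iio

    if dmpdp.form == "horizontal":
        gap = np.zeros((BLOCK, 2))
        parts = []
        for b in dmpdp.blocks:
            parts.extend([b, gap])
        mat = np.hstack(parts[:-1])
    else:
        mat = dmpdp.matrix
    lo, hi = mat.min(), mat.max()
    img = np.zeros_like(mat) if hi <= lo else (mat - lo) / (hi - lo)
    iio.imwrite(path, np.rint(img * 255).astype(np.uint8))
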