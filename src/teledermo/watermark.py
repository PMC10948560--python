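"""Compacted SVD watermarking of profile matrices in an audio carrier.

The carrier (optionally mapped into a transform domain) is cut into a
segment of exactly the payload's size, amplified by ``beta``, and reshaped
row-major into a matrix ``R``. The embedding chain is

    R = U S V^T                 (SVD of the carrier segment)
    D = S + alpha P             (payload P inserted into the singular values)
    D = U_w S_w V_w^T           (SVD of the perturbed matrix)
    R_w = U S_w V^T             (watermarked segment)

and the receiver, holding the side information {U_w, V_w, S}, inverts it:

    R_w* = U* S_w* V*^T         (SVD of the received segment)
    D*   = U_w S_w* V_w^T
    P*   = (D* - S) / alpha.

The scheme is exact on a clean channel (singular values are unique), and
non-blind: U_w, V_w and S must travel losslessly out of band. ``alpha``
trades carrier transparency against payload strength; ``beta`` amplifies
the embedding segment so that a fixed-power channel attack perturbs the
singular values relatively less. The carrier is recovered at the receiver
as U* S V*^T / beta.

Supported domains: ``time`` (identity), ``dct`` (orthonormal type-II),
``dst`` (the classic non-unitary DST-I pair with asymmetric normalization,
matching the convention behind the published domain comparison), and
``dwt`` (single-level discrete wavelet transform; the segment is cut from
the approximation band first).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pywt
from scipy import fft as sp_fft

from .errors import CapacityError, ParameterError, SideInfoMismatchError
from .profile import BLOCK, DMpDP

DOMAINS = ("time", "dct", "dst", "dwt")


@dataclass
class RPS:
    """Recorded patient-information signal: the 1-D audio carrier."""

    samples: np.ndarray
    sample_rate: float = 8000.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 49:
            raise ParameterError("carrier must be 1-D with >= 49 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("carrier contains non-finite values")


@dataclass
class WatermarkedRPS:
    """Watermarked carrier; same length and rate as the original."""

    samples: np.ndarray
    sample_rate: float = 8000.0


@dataclass
class EmbedConfig:
    """Embedding parameters.

    ``alpha`` scales the payload inside the singular values; ``beta``
    amplifies the carrier segment before the SVD; ``offset`` is the segment
    start in transform-coefficient order (for ``dwt``, within the
    approximation band).
    """

    domain: str = "dwt"
    alpha: float = 0.01
    beta: float = 1.0
    offset: int = 0
    wavelet: str = "db4"
    spacing: int = 25   # horizontal form: gap between blocks, in coefficients

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ParameterError(f"unknown domain {self.domain!r}")
        if self.alpha <= 0 or self.beta <= 0:
            raise ParameterError("alpha and beta must be positive")
        if self.offset < 0 or self.spacing < 0:
            raise ParameterError("offset and spacing must be >= 0")


@dataclass
class SideInfo:
    """Non-blind key material of one embedding.

    ``u_w``, ``v_w`` and ``s`` are lists with one entry per embedded matrix
    (a single entry except for the horizontal form). Layout metadata allows
    the receiver to disassemble the recovered payload.
    """

    u_w: list[np.ndarray]
    v_w: list[np.ndarray]
    s: list[np.ndarray]
    config: EmbedConfig
    form: str
    n_dps: int
    dp_order: list[str]
    shape: tuple[int, int]          # payload matrix shape (per block if horizontal)
    grid_rows: int | None = None
    n_samples: int = 0              # carrier length, for consistency checks

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        arrays = {"n_blocks": np.array(len(self.s))}
        for k, (u, v, s) in enumerate(zip(self.u_w, self.v_w, self.s)):
            arrays[f"u_{k}"], arrays[f"v_{k}"], arrays[f"s_{k}"] = u, v, s
        np.savez(
            path, **arrays,
            domain=self.config.domain, alpha=self.config.alpha,
            beta=self.config.beta, offset=self.config.offset,
            wavelet=self.config.wavelet, spacing=self.config.spacing,
            form=self.form, n_dps=self.n_dps,
            dp_order=np.array(self.dp_order), shape=np.array(self.shape),
            grid_rows=-1 if self.grid_rows is None else self.grid_rows,
            n_samples=self.n_samples)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SideInfo":
        with np.load(path, allow_pickle=False) as z:
            nb = int(z["n_blocks"])
            cfg = EmbedConfig(domain=str(z["domain"]), alpha=float(z["alpha"]),
                              beta=float(z["beta"]), offset=int(z["offset"]),
                              wavelet=str(z["wavelet"]),
                              spacing=int(z["spacing"]))
            rows = int(z["grid_rows"])
            return cls(
                u_w=[z[f"u_{k}"] for k in range(nb)],
                v_w=[z[f"v_{k}"] for k in range(nb)],
                s=[z[f"s_{k}"] for k in range(nb)],
                config=cfg, form=str(z["form"]), n_dps=int(z["n_dps"]),
                dp_order=[str(s) for s in z["dp_order"]],
                shape=tuple(int(x) for x in z["shape"]),
                grid_rows=None if rows < 0 else rows,
                n_samples=int(z["n_samples"]))


# ---------------------------------------------------------------------------
# transforms

def forward_transform(samples: np.ndarray, domain: str,
                      wavelet: str = "db4") -> tuple[np.ndarray, dict]:
    """Map a signal into the embedding domain.

    Returns the coefficient sequence and the metadata needed to invert it.
    For ``dwt`` the coefficients are the concatenation
    [approximation | detail]; ``usable`` marks how many leading
    coefficients may carry payload (the approximation band for dwt, the
    full length otherwise).
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if domain == "time":
        return x.copy(), {"domain": domain, "n": n, "usable": n}
    if domain == "dct":
        return sp_fft.dct(x, type=2, norm="ortho"), {
            "domain": domain, "n": n, "usable": n}
    if domain == "dst":
        # classic DST-I pair with asymmetric normalization: the forward
        # matrix M = dst1/2 satisfies M @ M = ((n+1)/2) I, inverted below
        # by dst1(X)/(n+1); deliberately NOT unitary (see module docstring)
        return sp_fft.dst(x, type=1) / 2.0, {
            "domain": domain, "n": n, "usable": n}
    if domain == "dwt":
        ca, cd = pywt.dwt(x, wavelet, mode="periodization")
        return np.concatenate([ca, cd]), {
            "domain": domain, "n": n, "usable": ca.size,
            "split": ca.size, "wavelet": wavelet}
    raise ParameterError(f"unknown domain {domain!r}")


def inverse_transform(coeffs: np.ndarray, meta: dict) -> np.ndarray:
    """Invert :func:`forward_transform` (round trip exact to ~1e-12)."""
    domain, n = meta["domain"], meta["n"]
    if domain == "time":
        return coeffs.copy()
    if domain == "dct":
        return sp_fft.idct(coeffs, type=2, norm="ortho")
    if domain == "dst":
        return sp_fft.dst(coeffs, type=1) / (n + 1.0)
    if domain == "dwt":
        split = meta["split"]
        x = pywt.idwt(coeffs[:split], coeffs[split:], meta["wavelet"],
                      mode="periodization")
        return x[:n]
    raise ParameterError(f"unknown domain {domain!r}")


# ---------------------------------------------------------------------------
# embed / extract

def _svd_insert(segment: np.ndarray, p: np.ndarray, alpha: float,
                beta: float) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                      np.ndarray]:
    """Run the embedding chain on one segment; returns (R_w flat, U_w, V_w, s)."""
    shape = p.shape
    r = (beta * segment).reshape(shape)
    u, s, vt = np.linalg.svd(r, full_matrices=False)
    d = _diag_embed(s, shape) + alpha * p
    u_w, s_w, v_wt = np.linalg.svd(d, full_matrices=False)
    r_w = (u * s_w) @ vt
    return r_w.ravel(), u_w, v_wt.T, s


def _diag_embed(s: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape)
    k = min(shape)
    out[np.arange(k), np.arange(k)] = s
    return out


def _payload(dmpdp: DMpDP) -> list[np.ndarray]:
    if dmpdp.form == "horizontal":
        return [np.asarray(b, dtype=float) for b in dmpdp.blocks]
    return [np.asarray(dmpdp.matrix, dtype=float)]


def _segment_bounds(side: SideInfo | None, cfg: EmbedConfig, form: str,
                    shapes: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Coefficient-domain (start, stop) of each embedded matrix."""
    bounds = []
    pos = cfg.offset
    for shape in shapes:
        size = shape[0] * shape[1]
        bounds.append((pos, pos + size))
        pos += size + (cfg.spacing if form == "horizontal" else 0)
    return bounds


def embed(rps: RPS, dmpdp: DMpDP, cfg: EmbedConfig) -> tuple[WatermarkedRPS,
                                                             SideInfo]:
    """Embed a DMpDP into a carrier; returns the watermarked signal and the
    side information required for extraction."""
    payload = _payload(dmpdp)
    coeffs, meta = forward_transform(rps.samples, cfg.domain, cfg.wavelet)
    bounds = _segment_bounds(None, cfg, dmpdp.form,
                             [p.shape for p in payload])
    if bounds[-1][1] > meta["usable"]:
        raise CapacityError(
            f"payload needs {bounds[-1][1]} coefficients, carrier offers "
            f"{meta['usable']} in the {cfg.domain} domain")

    u_ws, v_ws, ss = [], [], []
    for p, (start, stop) in zip(payload, bounds):
        flat, u_w, v_w, s = _svd_insert(coeffs[start:stop], p, cfg.alpha,
                                        cfg.beta)
        coeffs[start:stop] = flat
        u_ws.append(u_w)
        v_ws.append(v_w)
        ss.append(s)

    watermarked = inverse_transform(coeffs, meta)
    side = SideInfo(u_w=u_ws, v_w=v_ws, s=ss, config=cfg, form=dmpdp.form,
                    n_dps=dmpdp.n_dps, dp_order=list(dmpdp.dp_order),
                    shape=payload[0].shape, grid_rows=dmpdp.grid_rows,
                    n_samples=rps.samples.size)
    return WatermarkedRPS(samples=watermarked,
                          sample_rate=rps.sample_rate), side


def extract(received: WatermarkedRPS | RPS,
            side: SideInfo) -> tuple[np.ndarray | list[np.ndarray], RPS]:
    """De-embed the payload estimate P* and recover the carrier.

    Returns the payload matrix (or the list of 7x7 blocks for the
    horizontal form) and the recovered carrier signal.
    """
    cfg = side.config
    x = np.asarray(received.samples, dtype=float)
    if side.n_samples and x.size != side.n_samples:
        raise SideInfoMismatchError(
            f"received {x.size} samples, side info expects {side.n_samples}")
    coeffs, meta = forward_transform(x, cfg.domain, cfg.wavelet)

    if side.form == "horizontal":
        shapes = [(BLOCK, BLOCK)] * side.n_dps
    else:
        shapes = [side.shape]
    if len(shapes) != len(side.s):
        raise SideInfoMismatchError("side info block count mismatch")
    bounds = _segment_bounds(side, cfg, side.form, shapes)
    if bounds[-1][1] > meta["usable"]:
        raise SideInfoMismatchError("side info inconsistent with signal length")

    estimates = []
    for shape, (start, stop), u_w, v_w, s in zip(shapes, bounds, side.u_w,
                                                 side.v_w, side.s):
        r_w_star = coeffs[start:stop].reshape(shape)
        u_star, s_w_star, v_star_t = np.linalg.svd(r_w_star,
                                                   full_matrices=False)
        d_star = (u_w * s_w_star) @ v_w.T
        p_star = (d_star - _diag_embed(s, shape)) / cfg.alpha
        estimates.append(p_star)
        # carrier recovery: reinstate the original singular values and
        # undo the beta amplification
        r_hat = (u_star * s) @ v_star_t
        coeffs[start:stop] = r_hat.ravel() / cfg.beta

    recovered = RPS(samples=inverse_transform(coeffs, meta),
                    sample_rate=getattr(received, "sample_rate", 8000.0))
    if side.form == "horizontal":
        return estimates, recovered
    return estimates[0], recovered


def extracted_dmpdp(p_star: np.ndarray | list[np.ndarray],
                    side: SideInfo) -> DMpDP:
    """Wrap an extracted payload estimate with its layout metadata."""
    if side.form == "horizontal":
        return DMpDP(form=side.form, n_dps=side.n_dps,
                     dp_order=list(side.dp_order),
                     blocks=[np.asarray(b) for b in p_star],
                     spacing=side.config.spacing)
    return DMpDP(form=side.form, n_dps=side.n_dps,
                 dp_order=list(side.dp_order), matrix=np.asarray(p_star),
                 grid_rows=side.grid_rows)
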