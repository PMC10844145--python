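"""Signal conditioning for block-structured ROI panels.

Pipeline order (fixed): nuisance regression -> high-pass -> per-subject
centering -> same-condition concatenation with Gaussian boundary smoothing.
All stages are deterministic and shape-preserving until concatenation.

The high-pass is a projection onto the orthogonal complement of a discrete
cosine basis spanning frequencies below the cutoff, applied per block.  With
blocks of 100 volumes at TR = 1.6 s the cutoff period (0.009 Hz ~ 111 s)
is shorter than the block (160 s), so the removed subspace holds the DC term,
the drift-like first cosine, and any slower component; a projection (unlike an
IIR filter) has no edge transients on such short blocks and is bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft

from .simulate import Block, ConfoundSeries, RoiPanel


@dataclass
class ConcatenatedPanel:
    """Single-condition concatenation of preprocessed blocks.

    ``boundaries`` lists the start index of every block in ``matrix``
    (``boundaries[0] == 0``); ``order`` records the (subject_id, block_index)
    sequence used, so results are reproducible.
    """

    condition: str
    matrix: np.ndarray  # (n_total, N)
    boundaries: list[int]
    roi_labels: list[str]
    tr: float
    order: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("concatenated matrix contains non-finite values")
        if self.boundaries and self.boundaries[0] != 0:
            raise ValueError("boundaries[0] must be 0")

    @property
    def n_total(self) -> int:
        return self.matrix.shape[0]


def regress_confounds(panel: RoiPanel, confounds: ConfoundSeries) -> RoiPanel:
    """OLS residuals of each ROI series on [intercept, confound], per block."""
    out = []
    for b in panel.blocks:
        key = (b.subject_id, b.condition, b.block_index)
        if key not in confounds.series:
            raise ValueError(f"confound series missing for block {key}")
        c = confounds.get(key)
        if c.shape[0] != b.data.shape[0]:
            raise ValueError(f"confound length mismatch for block {key}")
        X = np.column_stack([np.ones_like(c), c])
        beta, *_ = np.linalg.lstsq(X, b.data, rcond=None)
        out.append(Block(b.subject_id, b.condition, b.block_index, b.data - X @ beta))
    return RoiPanel(blocks=out, roi_labels=panel.roi_labels, tr=panel.tr)


def _dct_cut(length: int, tr: float, cutoff_hz: float) -> int:
    """Number of leading DCT-II components (k = 0, 1, ...) below the cutoff.

    Component k of an orthonormal DCT-II over ``length`` samples oscillates at
    frequency k / (2 * length * tr) Hz.
    """
    k = int(np.ceil(2.0 * length * tr * cutoff_hz))
    return max(k, 1)  # always remove at least the DC term


def highpass(panel: RoiPanel, cutoff_hz: float = 0.009) -> RoiPanel:
    """Remove frequencies below ``cutoff_hz`` per block via DCT projection."""
    if cutoff_hz <= 0:
        raise ValueError("cutoff_hz must be > 0")
    out = []
    for b in panel.blocks:
        L = b.data.shape[0]
        k = _dct_cut(L, panel.tr, cutoff_hz)
        coef = sp_fft.dct(b.data, type=2, axis=0, norm="ortho")
        coef[:k] = 0.0
        out.append(Block(b.subject_id, b.condition, b.block_index, sp_fft.idct(coef, type=2, axis=0, norm="ortho")))
    return RoiPanel(blocks=out, roi_labels=panel.roi_labels, tr=panel.tr)


def center_per_subject(panel: RoiPanel, zscore: bool = False) -> RoiPanel:
    """Center each (subject, condition, ROI) series on its mean across that
    subject's same-condition samples.

    ``zscore=True`` additionally divides by the pooled standard deviation;
    the default preserves variance (the CI tests used downstream are
    scale-equivariant or rank-based, so rescaling is optional).
    """
    groups: dict[tuple[str, str], list[int]] = {}
    for i, b in enumerate(panel.blocks):
        groups.setdefault((b.subject_id, b.condition), []).append(i)
    out: list[Block | None] = [None] * len(panel.blocks)
    for (_, _), idxs in groups.items():
        stacked = np.vstack([panel.blocks[i].data for i in idxs])
        mean = stacked.mean(axis=0)
        sd = stacked.std(axis=0, ddof=0) if zscore else None
        for i in idxs:
            b = panel.blocks[i]
            d = b.data - mean
            if zscore:
                d = d / np.where(sd > 0, sd, 1.0)
            out[i] = Block(b.subject_id, b.condition, b.block_index, d)
    return RoiPanel(blocks=list(out), roi_labels=panel.roi_labels, tr=panel.tr)  # type: ignore[arg-type]


def _gaussian_weights(halfwidth: int = 2, sigma: float = 1.0) -> np.ndarray:
    k = np.arange(-halfwidth, halfwidth + 1)
    w = np.exp(-(k**2) / (2.0 * sigma**2))
    return w / w.sum()


def concatenate_blocks(
    panel: RoiPanel, condition: str, smooth_halfwidth: int = 5
) -> ConcatenatedPanel:
    """Join all blocks of one condition in (subject_id, block_index) order and
    smooth the first and last ``smooth_halfwidth`` samples of each block with a
    centered size-5 Gaussian moving average (sigma = 1 sample) computed within
    the concatenated series, so windows at a join mix adjacent blocks — the
    stated purpose of the smoothing.  Interior samples are untouched.
    """
    sel = sorted(
        (b for b in panel.blocks if b.condition == condition),
        key=lambda b: (b.subject_id, b.block_index),
    )
    if not sel:
        raise ValueError(f"no blocks of condition {condition!r}")
    mat = np.vstack([b.data for b in sel])
    L = sel[0].data.shape[0]
    boundaries = [i * L for i in range(len(sel))]
    w = _gaussian_weights(halfwidth=2, sigma=1.0)
    n = mat.shape[0]
    smoothed = mat.copy()
    edge_rows: list[int] = []
    for start in boundaries:
        edge_rows.extend(range(start, min(start + smooth_halfwidth, n)))
        edge_rows.extend(range(max(start + L - smooth_halfwidth, 0), min(start + L, n)))
    for t in sorted(set(edge_rows)):
        lo, hi = max(0, t - 2), min(n, t + 3)
        ww = w[(lo - (t - 2)) : (5 - ((t + 3) - hi))]
        smoothed[t] = (ww[:, None] * mat[lo:hi]).sum(axis=0) / ww.sum()
    return ConcatenatedPanel(
        condition=condition,
        matrix=smoothed,
        boundaries=boundaries,
        roi_labels=panel.roi_labels,
        tr=panel.tr,
        order=[(b.subject_id, b.block_index) for b in sel],
    )


def preprocess(
    panel: RoiPanel,
    confounds: ConfoundSeries | None,
    condition: str,
    cutoff_hz: float = 0.009,
    smooth_halfwidth: int = 5,
    zscore: bool = False,
) -> ConcatenatedPanel:
    """Full conditioning pipeline for one condition:
    regress -> highpass -> center -> concatenate."""
    p = panel
    if confounds is not None:
        p = regress_confounds(p, confounds)
    p = highpass(p, cutoff_hz=cutoff_hz)
    p = center_per_subject(p, zscore=zscore)
    return concatenate_blocks(p, condition, smooth_halfwidth=smooth_halfwidth)
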