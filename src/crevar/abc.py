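"""Activity-by-contact scoring of element-gene pairs.

The ABC model scores a candidate element ``e`` for a gene ``g`` as the
product of the element's activity (geometric mean of ATAC and H3K27ac
signal) and its normalized contact frequency with the gene's TSS,
normalized over all candidate elements within the scoring window:

    ABC(e, g) = A_e * C_eg / sum_{e' in window} A_e' * C_e'g

Contacts are read from a symmetric binned contact matrix (5-kb bins by
default) and offset by a pseudocount (the smallest nonzero contact in
the window) so zero-contact bins are not silently excluded. Connections
are called at score > 0.025 with element and TSS at least 500 bp apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD = 0.025
DEFAULT_MIN_DIST = 500
DEFAULT_WINDOW = 5_000_000


@dataclass
class ContactMatrix:
    """Symmetric nonnegative contact matrix over fixed-size bins."""

    chrom: str
    bin_size: int
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.bin_size <= 0:
            raise ValueError("bin size must be positive")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("contact matrix must be symmetric")
        if np.any(self.matrix < 0):
            raise ValueError("contacts must be nonnegative")

    def bin_of(self, pos) -> np.ndarray:
        b = np.asarray(pos) // self.bin_size
        return np.clip(b, 0, self.matrix.shape[0] - 1).astype(int)


def element_activity(atac, h3k27ac) -> np.ndarray:
    """Geometric mean of the two activity signals."""
    atac = np.asarray(atac, dtype=float)
    h3k27ac = np.asarray(h3k27ac, dtype=float)
    if np.any(atac < 0) or np.any(h3k27ac < 0):
        raise ValueError("activities must be nonnegative")
    return np.sqrt(atac * h3k27ac)


def abc_scores(
    elements: pd.DataFrame,
    contacts: ContactMatrix,
    gene_tss: int,
    gene_chrom: str | None = None,
    window: int = DEFAULT_WINDOW,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Score every element within ``window`` of the TSS for one gene.

    ``elements`` needs chrom/start/end/name plus either an ``activity``
    column or ``atac``/``h3k27ac`` columns. Scores over the window
    (denominator) set sum to 1; a zero denominator yields all-zero
    scores with a warning.
    """
    el = elements.copy()
    if gene_chrom is not None:
        el = el[el["chrom"] == gene_chrom].copy()
    if "activity" not in el:
        el["activity"] = element_activity(el["atac"], el["h3k27ac"])
    mid = (el["start"] + el["end"]) // 2
    el["distance"] = (mid - gene_tss).abs()
    el = el[el["distance"] <= window].copy()
    if el.empty:
        return el.assign(score=pd.Series(dtype=float))
    tss_bin = contacts.bin_of(gene_tss)
    raw_contact = contacts.matrix[contacts.bin_of(mid.loc[el.index]), tss_bin]
    if pseudocount is None:
        nz = raw_contact[raw_contact > 0]
        pseudocount = float(nz.min()) if len(nz) else 1e-6
    products = el["activity"].to_numpy() * (raw_contact + pseudocount)
    denom = products.sum()
    if denom <= 0:
        warnings.warn("zero ABC denominator; all scores set to 0")
        el["score"] = 0.0
    else:
        el["score"] = products / denom
    return el.reset_index(drop=True)


def call_connections(
    scores: pd.DataFrame,
    gene: str,
    threshold: float = DEFAULT_THRESHOLD,
    min_dist: int = DEFAULT_MIN_DIST,
) -> pd.DataFrame:
    """Keep elements with score strictly above threshold and >=500 bp away."""
    keep = scores[(scores["score"] > threshold) & (scores["distance"] >= min_dist)]
    out = keep[["chrom", "start", "end", "name", "score", "distance"]].copy()
    out.insert(4, "gene_id", gene)
    return out.reset_index(drop=True)


def score_all_genes(
    elements: pd.DataFrame,
    contacts: dict,
    genes: pd.DataFrame,
    bin_size: int,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    min_dist: int = DEFAULT_MIN_DIST,
) -> pd.DataFrame:
    """Call ABC connections for every gene in a TSS table.

    ``contacts`` maps chromosome name to a symmetric matrix (or a
    :class:`ContactMatrix`); cross-chromosome pairs are never scored.
    """
    calls = []
    for _, g in genes.iterrows():
        cm = contacts[g["chrom"]]
        if not isinstance(cm, ContactMatrix):
            cm = ContactMatrix(g["chrom"], bin_size, cm)
        scored = abc_scores(elements, cm, int(g["tss"]), gene_chrom=g["chrom"],
                            window=window)
        if scored.empty:
            continue
        calls.append(call_connections(scored, g["name"], threshold, min_dist))
    if not calls:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "name", "gene_id", "score", "distance"]
        )
    return pd.concat(calls, ignore_index=True)
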