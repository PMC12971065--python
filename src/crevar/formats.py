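"""Readers and writers for the plain-text interchange formats.

Conventions (applied everywhere in the package):

* genomic intervals are BED-style 0-based half-open ``[start, end)``;
* genes are BED6 records whose interval is the transcript span; the TSS
  is the ``start`` coordinate for ``+`` strand genes and ``end - 1`` for
  ``-`` strand genes;
* variants are exchanged as minimal VCF v4.2 (CHROM POS ID REF ALT) with
  1-based POS converted to the internal 0-based convention on read;
* count matrices are sparse triplet TSV (feature_id, cell_id, count);
* loops are BEDPE (six coordinate columns plus a name);
* tables are TSV with a header row, floats serialized at 6 significant
  digits so that runs are byte-reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

FLOAT_FORMAT = "%.6g"

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(df: pd.DataFrame, path) -> None:
    """Write a BED6 file from a frame with chrom/start/end/name[/score/strand]."""
    out = df.copy()
    if "score" not in out:
        out["score"] = 0
    if "strand" not in out:
        out["strand"] = "."
    out[BED6_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(BED6_COLUMNS)]
    df.columns = BED6_COLUMNS[: df.shape[1]]
    return df


def gene_tss(genes: pd.DataFrame) -> pd.Series:
    """TSS coordinate per gene: start on '+', end - 1 on '-'."""
    missing = ~genes["strand"].isin(["+", "-"])
    if missing.any():
        raise ValueError(
            f"genes without a usable strand: {genes.loc[missing, 'name'].tolist()}"
        )
    return genes["start"].where(genes["strand"] == "+", genes["end"] - 1)


def write_triplet_matrix(matrix: np.ndarray, feature_ids, cell_ids, path) -> None:
    """Sparse triplet TSV (feature_id, cell_id, count); zeros are omitted."""
    matrix = np.asarray(matrix)  # cells x features orientation
    cells, feats = np.nonzero(matrix)
    df = pd.DataFrame(
        {
            "feature_id": np.asarray(feature_ids)[feats],
            "cell_id": np.asarray(cell_ids)[cells],
            "count": matrix[cells, feats],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_triplet_matrix(path, feature_ids=None, cell_ids=None):
    """Reconstruct a dense cells x features array from triplet TSV.

    Row/column universes default to the ids present in the file (sorted);
    passing them explicitly preserves all-zero rows and columns.
    """
    df = pd.read_csv(path, sep="\t")
    if feature_ids is None:
        feature_ids = sorted(df["feature_id"].unique())
    if cell_ids is None:
        cell_ids = sorted(df["cell_id"].unique())
    f_idx = {f: i for i, f in enumerate(feature_ids)}
    c_idx = {c: i for i, c in enumerate(cell_ids)}
    mat = np.zeros((len(cell_ids), len(feature_ids)))
    mat[df["cell_id"].map(c_idx), df["feature_id"].map(f_idx)] = df["count"].to_numpy()
    return mat, list(feature_ids), list(cell_ids)


VCF_HEADER = "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\n"


def write_vcf(variants: pd.DataFrame, path) -> None:
    """Minimal VCF v4.2; internal 0-based positions become 1-based POS."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for row in variants.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos + 1}\t{row.id}\t{row.ref}\t{row.alt}\n")


def read_vcf(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, vid, ref, alt = line.rstrip("\n").split("\t")[:5]
            rows.append((chrom, int(pos) - 1, vid, ref, alt))
    return pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])


BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2", "name",
]


def write_bedpe(loops: pd.DataFrame, path) -> None:
    loops[BEDPE_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_bedpe(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(BEDPE_COLUMNS)]
    df.columns = BEDPE_COLUMNS[: df.shape[1]]
    return df


def write_truth(truth: dict, path) -> None:
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, set):
            return sorted(obj)
        raise TypeError(f"unserializable {type(obj)}")

    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True, default=_default))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def write_contact_matrix(matrix: np.ndarray, path) -> None:
    """Dense contact matrix as triplet TSV (bin_i, bin_j, value), i <= j."""
    iu = np.triu_indices(matrix.shape[0])
    vals = matrix[iu]
    keep = vals != 0
    df = pd.DataFrame({"bin_i": iu[0][keep], "bin_j": iu[1][keep], "value": vals[keep]})
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_contact_matrix(path, n_bins: int) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    mat = np.zeros((n_bins, n_bins))
    mat[df["bin_i"], df["bin_j"]] = df["value"]
    mat[df["bin_j"], df["bin_i"]] = df["value"]
    return mat
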