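"""Protein families by thresholded single-linkage clustering of pairwise hits.

Two sequences join the same family when they are connected (directly or
transitively) by hits passing all three screens: E-value strictly below
1e-4, identity at least 35%, and the alignment covering at least 70% of
*both* sequence lengths.  Families are the connected components of the
surviving undirected graph; sequences with no surviving edge become
singleton families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "FilterThresholds",
    "FamilySet",
    "read_hits",
    "read_lengths",
    "read_seq2genome",
    "filter_hits",
    "cluster_families",
    "build_occurrence_matrix",
    "write_families",
    "write_occurrence_matrix",
]

_HIT_COLUMNS = ["query", "subject", "pident", "length", "evalue"]
# BLAST outfmt-6 column order
_OUTFMT6 = [
    "query",
    "subject",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


@dataclass(frozen=True)
class FilterThresholds:
    """Hit screens: identity >= min_identity, E < max_evalue (strict),
    alignment length >= min_coverage * length of BOTH partners."""

    min_identity: float = 35.0
    min_coverage: float = 0.70
    max_evalue: float = 1e-4

    def __post_init__(self):
        if not 0 <= self.min_identity <= 100:
            raise ValueError("min_identity must be in [0, 100]")
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage must be in (0, 1]")
        if self.max_evalue < 0:
            raise ValueError("max_evalue must be >= 0")


def read_lengths(path) -> dict[str, int]:
    """TSV: sequence id, residue length."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 columns")
            length = int(parts[1])
            if length <= 0:
                raise ValueError(f"{path}:{ln}: nonpositive length for {parts[0]}")
            out[parts[0]] = length
    return out


def read_seq2genome(path) -> dict[str, str]:
    """TSV: sequence id, genome id."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 columns")
            out[parts[0]] = parts[1]
    return out


def read_hits(path, lengths: dict[str, int]) -> pd.DataFrame:
    """Parse a BLAST-tabular hit file (outfmt-6 or the 5-column minimum).

    Self-hits are retained here (they never create edges downstream).
    Malformed rows raise with their line number; every sequence id must
    have an entry in ``lengths``.
    """
    with open(path) as fh:
        first = fh.readline()
    ncol = len(first.rstrip("\n").split("\t")) if first.strip() else 0
    if ncol >= len(_OUTFMT6):
        names = _OUTFMT6 + [f"extra{i}" for i in range(ncol - len(_OUTFMT6))]
    elif ncol >= 5:
        names = _HIT_COLUMNS + [f"extra{i}" for i in range(ncol - 5)]
    else:
        raise ValueError(f"{path}: expected >= 5 tab-separated columns, got {ncol}")
    df = pd.read_csv(
        path, sep="\t", names=names, header=None, comment="#", dtype=str,
        keep_default_na=False,
    )
    for col in ("pident", "length", "evalue"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna()]
        if len(bad):
            raise ValueError(
                f"{path}: malformed {col} value {df.loc[bad[0], col]!r} at line {bad[0] + 1}"
            )
        df[col] = parsed
    df = df[_HIT_COLUMNS].copy()
    ids = set(df["query"]).union(df["subject"])
    missing = ids - set(lengths)
    if missing:
        raise KeyError(f"missing sequence length for: {sorted(missing)[:5]}")
    df["qlen"] = df["query"].map(lengths)
    df["slen"] = df["subject"].map(lengths)
    if (df["pident"] < 0).any() or (df["pident"] > 100).any():
        raise ValueError(f"{path}: identity outside [0, 100]")
    return df


def filter_hits(hits: pd.DataFrame, thresholds: FilterThresholds | None = None) -> pd.DataFrame:
    """Apply the screens and return a deduplicated undirected edge list.

    Kept iff query != subject, E < max_evalue (strict), identity >=
    min_identity, and alignment length >= min_coverage * each partner's
    length.  Best hit per ordered pair is retained before symmetrization;
    reciprocal duplicates keep the best E-value.
    """
    th = thresholds or FilterThresholds()
    keep = (
        (hits["query"] != hits["subject"])
        & (hits["evalue"] < th.max_evalue)
        & (hits["pident"] >= th.min_identity)
        & (hits["length"] >= th.min_coverage * hits["qlen"])
        & (hits["length"] >= th.min_coverage * hits["slen"])
    )
    edges = hits.loc[keep, ["query", "subject", "evalue"]].copy()
    edges = edges.sort_values("evalue", kind="stable")
    edges = edges.drop_duplicates(subset=["query", "subject"], keep="first")
    q = edges["query"].to_numpy(dtype=str)
    s = edges["subject"].to_numpy(dtype=str)
    a = np.where(q <= s, q, s)
    b = np.where(q <= s, s, q)
    edges = edges.assign(a=a, b=b).drop_duplicates(subset=["a", "b"], keep="first")
    return edges[["a", "b", "evalue"]].rename(columns={"a": "seq1", "b": "seq2"}).reset_index(
        drop=True
    )


@dataclass
class FamilySet:
    """A partition of the sequence universe into families."""

    families: dict[str, set[str]]  # family id -> member sequence ids
    membership: dict[str, str]  # sequence id -> family id

    def __post_init__(self):
        total = sum(len(m) for m in self.families.values())
        if total != len(self.membership):
            raise ValueError("families do not partition the universe")

    @property
    def n_families(self) -> int:
        return len(self.families)


def _family_ids(components: list[set[str]]) -> list[str]:
    width = max(6, len(str(len(components))))
    return [f"FAM{i + 1:0{width}d}" for i in range(len(components))]


def cluster_families(universe, edges: pd.DataFrame) -> FamilySet:
    """Connected components of the filtered hit graph.

    Family ids are FAM + zero-padded rank, ordered by decreasing size then
    by lexicographically smallest member, so the labelling is independent
    of input order.
    """
    ids = sorted(set(universe))
    index = {s: i for i, s in enumerate(ids)}
    if len(edges):
        for col in ("seq1", "seq2"):
            outside = set(edges[col]) - set(index)
            if outside:
                raise KeyError(f"edge endpoint outside universe: {sorted(outside)[:5]}")
        r = edges["seq1"].map(index).to_numpy()
        c = edges["seq2"].map(index).to_numpy()
        data = np.ones(len(r), dtype=np.int8)
        graph = coo_matrix((data, (r, c)), shape=(len(ids), len(ids)))
    else:
        graph = coo_matrix((len(ids), len(ids)), dtype=np.int8)
    n_comp, labels = connected_components(graph, directed=False)
    comps: dict[int, set[str]] = {}
    for s, lab in zip(ids, labels):
        comps.setdefault(int(lab), set()).add(s)
    ordered = sorted(comps.values(), key=lambda m: (-len(m), min(m)))
    fam_ids = _family_ids(ordered)
    families = dict(zip(fam_ids, ordered))
    membership = {s: fid for fid, members in families.items() for s in members}
    return FamilySet(families, membership)


def build_occurrence_matrix(fams: FamilySet, seq2genome: dict[str, str]) -> pd.DataFrame:
    """Genomes x families matrix of copy counts."""
    unmapped = set(fams.membership) - set(seq2genome)
    if unmapped:
        raise KeyError(f"unmapped sequence ids: {sorted(unmapped)[:5]}")
    df = pd.DataFrame(
        {
            "genome": [seq2genome[s] for s in fams.membership],
            "family": [fams.membership[s] for s in fams.membership],
        }
    )
    mat = df.groupby(["genome", "family"]).size().unstack(fill_value=0)
    mat = mat.reindex(sorted(mat.index), axis=0).reindex(sorted(fams.families), axis=1, fill_value=0)
    mat.index.name = "genome"
    mat.columns.name = "family"
    return mat


def write_families(fams: FamilySet, path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tfamily\n")
        for seq in sorted(fams.membership):
            fh.write(f"{seq}\t{fams.membership[seq]}\n")


def write_occurrence_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")
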